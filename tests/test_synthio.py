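"""Synthetic-data generator: determinism, planted ground truth, labels."""

import numpy as np
import pandas as pd
import pytest

from mipepscan.fly_stats import balancer_intercross
from mipepscan.orfscan import find_orfs
from mipepscan.ribomatch import translate3
from mipepscan.synthio import (
    SimConfig, TranscriptRecord, simulate_counts, simulate_phenotypes,
    simulate_progeny, simulate_ribopeptides, simulate_transcriptome,
)


def single_class_config(**kwargs):
    classes = {"CDS": 0, "UTR5": 0, "UTR3": 0, "lncRNA": 0, "pri_miR": 0}
    classes.update(kwargs.pop("n_per_class"))
    return SimConfig(n_per_class=classes, **kwargs)


def test_config_invariants():
    with pytest.raises(ValueError):
        SimConfig(frac_specific_A=0.5, frac_specific_B=0.4, frac_shared=0.2)
    with pytest.raises(ValueError):
        SimConfig(dispersion=0.0)


def test_transcript_record_invariants():
    with pytest.raises(ValueError):
        TranscriptRecord("t", "pri_miR", "ACGT", premir_interval=(2, 10))
    with pytest.raises(ValueError):
        TranscriptRecord("t", "mRNA", "ACGT")


def test_determinism_identical_outputs():
    a = simulate_transcriptome(SimConfig(seed=7))
    b = simulate_transcriptome(SimConfig(seed=7))
    assert [t.sequence for t in a[0]] == [t.sequence for t in b[0]]
    pd.testing.assert_frame_equal(a[1], b[1])
    c = simulate_transcriptome(SimConfig(seed=8))
    assert [t.sequence for t in a[0]] != [t.sequence for t in c[0]]


def test_zero_rate_class_has_no_planted_orfs():
    cfg = single_class_config(
        n_per_class={"lncRNA": 10},
        orf_rate={"CDS": 0, "UTR5": 0, "UTR3": 0, "lncRNA": 0.0, "pri_miR": 0},
    )
    _, truth = simulate_transcriptome(cfg)
    assert truth.empty


def test_planted_count_within_poisson_bound():
    """orf_rate 2/kb on 100 x 1 kb transcripts: total planted within 3 sigma
    of the Poisson expectation of 200."""
    cfg = single_class_config(
        n_per_class={"lncRNA": 100},
        length_range={"CDS": (600, 2000), "UTR5": (150, 600), "UTR3": (300, 1000),
                      "lncRNA": (1000, 1000), "pri_miR": (500, 1500)},
        orf_rate={"CDS": 0, "UTR5": 0, "UTR3": 0, "lncRNA": 2.0, "pri_miR": 0},
        seed=5,
    )
    _, truth = simulate_transcriptome(cfg)
    assert abs(len(truth) - 200) <= 3 * np.sqrt(200)


def test_too_short_class_rejected():
    cfg_kwargs = dict(
        n_per_class={"CDS": 0, "UTR5": 5, "UTR3": 0, "lncRNA": 0, "pri_miR": 0},
        length_range={"CDS": (600, 2000), "UTR5": (30, 60), "UTR3": (300, 1000),
                      "lncRNA": (500, 2000), "pri_miR": (500, 1500)},
    )
    with pytest.raises(ValueError, match="UTR5"):
        simulate_transcriptome(SimConfig(**cfg_kwargs))


def test_every_planted_orf_is_detectable(transcriptome):
    """Ground-truth consistency: each planted ORF appears in find_orfs
    'all'-mode output on its emitted sequence."""
    transcripts, truth = transcriptome
    seqs = {t.id: t.sequence for t in transcripts}
    for tid, grp in truth.groupby("transcript_id"):
        found = {(h.frame, h.start_nt, h.end_nt)
                 for h in find_orfs(seqs[tid], min_aa=10, mode="all")}
        for row in grp.itertuples():
            assert (row.frame, row.start_nt, row.end_nt) in found


def test_primir_geometry(transcriptome):
    transcripts, truth = transcriptome
    planted = truth.groupby("transcript_id")["end_nt"].max()
    for t in transcripts:
        if t.rna_class != "pri_miR":
            assert t.premir_interval is None
            continue
        assert t.premir_interval is not None
        s, e = t.premir_interval
        assert 0 <= s < e <= len(t.sequence)
        # at least one planted ORF, all wholly 5' of the pre-miR
        assert t.id in planted.index
        assert planted[t.id] <= s


def test_truth_peptides_are_orf_translations(transcriptome):
    transcripts, truth = transcriptome
    seqs = {t.id: t.sequence for t in transcripts}
    sample = truth.sample(50, random_state=0) if len(truth) > 50 else truth
    for row in sample.itertuples():
        tr = translate3(seqs[row.transcript_id])[row.frame]
        off = (row.start_nt - row.frame) // 3
        assert tr.peptide_string[off : off + row.aa_len] == row.peptide
        assert row.peptide.startswith("M") and "*" not in row.peptide


def test_peptides_all_true_all_matchable(transcriptome):
    transcripts, truth = transcriptome
    cfg = SimConfig(seed=7, n_peptides=50, peptide_true_fraction=1.0)
    peps = simulate_ribopeptides(cfg, truth, transcripts)
    assert peps.is_true.all()
    translations = [tr.peptide_string for t in transcripts
                    for tr in translate3(t.sequence)]
    for pep in peps.sequence:
        assert any(pep in s for s in translations)


def test_peptides_all_decoys(transcriptome):
    transcripts, truth = transcriptome
    cfg = SimConfig(seed=7, n_peptides=30, peptide_true_fraction=0.0)
    peps = simulate_ribopeptides(cfg, truth, transcripts)
    assert (~peps.is_true).all()


def test_decoy_purity_brute_force(peptide_set, transcriptome):
    transcripts, _ = transcriptome
    translations = [tr.peptide_string for t in transcripts
                    for tr in translate3(t.sequence)]
    decoys = peptide_set.loc[~peptide_set.is_true, "sequence"]
    for pep in decoys:
        assert not any(pep in s for s in translations)


def test_true_peptides_without_truth_error():
    cfg = SimConfig(seed=1, peptide_true_fraction=0.5)
    with pytest.raises(ValueError, match="empty"):
        simulate_ribopeptides(cfg, pd.DataFrame(columns=["aa_len"]), [])


def test_counts_determinism_and_shape():
    cfg = SimConfig(seed=3, n_genes=300)
    (cm1, lab1), (cm2, lab2) = simulate_counts(cfg), simulate_counts(cfg)
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
    pd.testing.assert_frame_equal(lab1, lab2)
    assert cm1.counts.shape == (300, 15)
    assert set(cm1.conditions) == {"ctrl", "miR_like", "miPEP_like"}


def test_counts_library_totals_near_configured_size():
    cfg = SimConfig(seed=13, effect_logfc=0.0)
    cm, _ = simulate_counts(cfg)
    totals = cm.counts.sum(axis=0).to_numpy(float)
    lo, hi = cfg.lib_size_range
    # 4 sigma of the NB total is ~5% here; allow 6% beyond the range ends
    assert (totals > lo * 0.94).all() and (totals < hi * 1.06).all()


def test_counts_label_fractions():
    cfg = SimConfig(seed=2, n_genes=2000)
    _, labels = simulate_counts(cfg)
    vc = labels.group.value_counts()
    assert vc["shared"] == round(2000 * cfg.frac_shared)
    assert vc["B_specific"] == round(2000 * cfg.frac_specific_B)
    # planted shared fraction of B's regulated set is 24%
    assert vc["shared"] / (vc["shared"] + vc["B_specific"]) == pytest.approx(0.24)


def test_counts_reps_validation():
    with pytest.raises(ValueError, match="n_reps"):
        simulate_counts(SimConfig(n_reps=1))


def test_progeny_neutral_matches_expectation():
    counts = simulate_progeny(balancer_intercross(), 30000, seed=1)
    assert counts["KI/KI"] / 30000 == pytest.approx(1 / 3, abs=0.02)


def test_progeny_zero_viability_class_absent():
    counts = simulate_progeny(balancer_intercross(), 500,
                              effect={"KI/KI": 0.0}, seed=1)
    assert counts["KI/KI"] == 0 and counts["KI/CyO"] == 500


def test_progeny_reproducible_and_validated():
    a = simulate_progeny(balancer_intercross(), 100, seed=9)
    b = simulate_progeny(balancer_intercross(), 100, seed=9)
    assert a == b
    with pytest.raises(ValueError):
        simulate_progeny(balancer_intercross(), 0)


def test_phenotypes_shift_and_tails():
    cfg = SimConfig(seed=4, phenotype_n=500, phenotype_effect=2.0)
    data = simulate_phenotypes(cfg)
    assert set(data) == {"control", "affected"}
    assert data["control"].mean() - data["affected"].mean() == pytest.approx(2.0, abs=0.3)
    heavy = simulate_phenotypes(cfg, heavy_tailed=True)
    # t(3) noise has excess kurtosis relative to the normal draw
    from scipy.stats import kurtosis
    assert kurtosis(heavy["control"]) > kurtosis(data["control"])
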