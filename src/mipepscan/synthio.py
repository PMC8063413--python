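"""Synthetic data generation for every pipeline stage.

The generator plants known structure — ORFs in class-labelled transcripts,
true/decoy ribo-seq peptides, negative-binomial count matrices with
condition-specific and co-regulated differential-expression sets,
multinomial progeny counts under cross schemes, grouped phenotype
measurements — so that recall/precision, calibration and recovery can be
scored against ground truth.

Background sequence outside planted ORFs is i.i.d. uniform ACGT with a
stop-codon cassette (stops in all three frames) injected every 30 nt, so
spurious ORFs of >= 10 aa are rare and the planted set is close to the
detectable set.  All randomness flows from one seeded generator per
simulator invocation; identical (seed, config) gives identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .de_partition import CountMatrix
from .fly_stats import CrossScheme, expected_fractions
from .ribomatch import translate3

RNA_CLASSES = ("CDS", "UTR5", "UTR3", "lncRNA", "pri_miR")

# 11-nt cassette with stop codons at offsets 0, 4 and 8 — one per frame
STOP_CASSETTE = "TAAATAAATAA"

SENSE_CODONS_NO_ATG = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]

PREMIR_LEN = 80  # typical pre-miR hairpin extent, nt


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with its RNA class and, for pri-miRs, the
    pre-miR sub-interval (0-based half-open, sense strand)."""

    id: str
    rna_class: str
    sequence: str
    premir_interval: Optional[tuple[int, int]] = None
    source_coords: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if self.premir_interval is not None:
            s, e = self.premir_interval
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError("premir_interval outside transcript")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the generator emulates (class-ordered ORF densities, a 24%
    co-regulated share of condition B's planted set, |log2FC| 1.5 at NB
    dispersion 0.1, five replicates per condition)."""

    seed: int = 0
    # transcriptome
    n_per_class: dict = field(default_factory=lambda: {
        "CDS": 40, "UTR5": 60, "UTR3": 60, "lncRNA": 50, "pri_miR": 50,
    })
    length_range: dict = field(default_factory=lambda: {
        "CDS": (600, 2000), "UTR5": (150, 600), "UTR3": (300, 1000),
        "lncRNA": (500, 2000), "pri_miR": (500, 1500),
    })
    orf_rate: dict = field(default_factory=lambda: {
        "CDS": 4.0, "UTR5": 0.5, "UTR3": 0.5, "lncRNA": 2.0, "pri_miR": 2.0,
    })
    min_aa: int = 10
    orf_aa_range: tuple[int, int] = (10, 40)
    # ribo peptides
    n_peptides: int = 200
    peptide_true_fraction: float = 0.5
    peptide_len_range: tuple[int, int] = (7, 17)
    # counts
    n_genes: int = 2000
    n_reps: int = 5
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    frac_specific_A: float = 0.060
    frac_specific_B: float = 0.076
    frac_shared: float = 0.024
    effect_logfc: float = 1.5
    # progeny / phenotypes
    progeny_n: int = 100
    phenotype_effect: float = 1.0
    phenotype_sd: float = 1.0
    phenotype_n: int = 25

    def __post_init__(self) -> None:
        if self.frac_specific_A + self.frac_specific_B + self.frac_shared > 1:
            raise ValueError("DE fractions must sum to <= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_genes <= 0 or self.n_peptides < 0:
            raise ValueError("counts must be positive")
        for cls, (lo, hi) in self.length_range.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad length range for {cls}")

    def config_hash(self) -> str:
        return hashlib.md5(repr(sorted(asdict(self).items())).encode()).hexdigest()[:12]


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    # distinct, reproducible stream per simulator
    return np.random.default_rng([config_seed, stream])


# ---------------------------------------------------------------------------
# Transcriptome

def _background(rng: np.random.Generator, length: int) -> list[str]:
    seq = list(rng.choice(list("ACGT"), size=length))
    for start in range(0, length - len(STOP_CASSETTE) + 1, 30):
        seq[start : start + len(STOP_CASSETTE)] = STOP_CASSETTE
    return seq


def _plant_orfs(
    rng: np.random.Generator,
    seq: list[str],
    region_end: int,
    n_orfs: int,
    aa_range: tuple[int, int],
) -> list[dict]:
    """Overwrite non-overlapping sub-intervals of seq[0:region_end] with
    complete ORFs (ATG + sense codons + stop); returns their records."""
    placed: list[tuple[int, int]] = []
    records = []
    attempts = 0
    while len(records) < n_orfs and attempts < 200 * max(n_orfs, 1):
        attempts += 1
        aa_len = int(rng.integers(aa_range[0], aa_range[1] + 1))
        nt_len = 3 * aa_len + 3
        if nt_len > region_end:
            continue
        start = int(rng.integers(0, region_end - nt_len + 1))
        end = start + nt_len
        if any(s < end and start < e for s, e in placed):
            continue
        codons = ["ATG"] + [
            SENSE_CODONS_NO_ATG[i]
            for i in rng.integers(0, len(SENSE_CODONS_NO_ATG), size=aa_len - 1)
        ] + [("TAA", "TAG", "TGA")[rng.integers(0, 3)]]
        seq[start:end] = "".join(codons)
        placed.append((start, end))
        records.append({"start_nt": start, "end_nt": end, "aa_len": aa_len,
                        "frame": start % 3})
    return records


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Generate class-labelled transcripts with Poisson-planted ORFs.

    Planted ORF counts per transcript are Poisson(orf_rate x kb of
    plantable region).  pri_miR transcripts carry a pre-miR interval in
    their 3' region; their planted ORFs lie wholly 5' of it, at least one
    per transcript whenever the class rate is positive.  Returns the
    transcripts and a ground-truth table of every planted ORF.
    """
    rng = _rng(config.seed, 1)
    max_orf_nt = 3 * config.orf_aa_range[1] + 6
    for cls, (lo, _hi) in config.length_range.items():
        rate = config.orf_rate.get(cls, 0.0)
        avail = lo - (PREMIR_LEN if cls == "pri_miR" else 0)
        if rate > 0 and avail < max_orf_nt:
            raise ValueError(
                f"class {cls}: minimum length {lo} too short to host a planted ORF"
            )

    transcripts: list[TranscriptRecord] = []
    truth_rows = []
    for cls in RNA_CLASSES:
        n = config.n_per_class.get(cls, 0)
        lo, hi = config.length_range[cls]
        rate = config.orf_rate.get(cls, 0.0)
        for i in range(n):
            tid = f"{cls}_{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            seq = _background(rng, length)
            premir: Optional[tuple[int, int]] = None
            if cls == "pri_miR":
                premir_start = int(length * 0.7)
                premir = (premir_start, min(premir_start + PREMIR_LEN, length))
                region_end = premir_start
            else:
                region_end = length
            n_orfs = 0
            if rate > 0:
                n_orfs = int(rng.poisson(rate * region_end / 1000.0))
                if cls == "pri_miR":
                    n_orfs = max(1, n_orfs)
            orfs = _plant_orfs(rng, seq, region_end, n_orfs, config.orf_aa_range)
            sequence = "".join(seq)
            transcripts.append(
                TranscriptRecord(tid, cls, sequence, premir_interval=premir)
            )
            for rec in orfs:
                pep = translate3(sequence, tid)[rec["frame"]].peptide_string[
                    (rec["start_nt"] - rec["frame"]) // 3 :
                    (rec["start_nt"] - rec["frame"]) // 3 + rec["aa_len"]
                ]
                truth_rows.append({"transcript_id": tid, "rna_class": cls, **rec,
                                   "peptide": pep})
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "rna_class", "start_nt", "end_nt", "aa_len",
                 "frame", "peptide"],
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Ribo-seq peptide sets

def simulate_ribopeptides(
    config: SimConfig,
    truth: pd.DataFrame,
    transcripts: Sequence[TranscriptRecord],
) -> pd.DataFrame:
    """Draw a labelled peptide set: a ``peptide_true_fraction`` share are
    exact substrings of planted-ORF peptides; the rest are residue-shuffled
    decoys rejection-sampled to be absent from every three-frame
    translation of every transcript."""
    rng = _rng(config.seed, 2)
    n_true = int(round(config.n_peptides * config.peptide_true_fraction))
    n_decoy = config.n_peptides - n_true
    lo, hi = config.peptide_len_range
    usable = truth[truth["aa_len"] >= lo] if len(truth) else truth
    if n_true > 0 and (truth is None or len(usable) == 0):
        raise ValueError("requested true peptides but ground truth is empty")

    translations = [
        tr.peptide_string for t in transcripts for tr in translate3(t.sequence, t.id)
    ]

    def _in_any_translation(pep: str) -> bool:
        return any(pep in s for s in translations)

    rows = []
    for k in range(n_true):
        src = usable.iloc[int(rng.integers(0, len(usable)))]
        pep_len = int(rng.integers(lo, min(hi, src["aa_len"]) + 1))
        start = int(rng.integers(0, src["aa_len"] - pep_len + 1))
        pep = src["peptide"][start : start + pep_len]
        rows.append({"peptide_id": f"pep_true_{k:04d}", "sequence": pep,
                     "is_true": True, "source_transcript": src["transcript_id"]})
    for k in range(n_decoy):
        template = None
        if rows and rng.random() < 0.5:
            template = rows[int(rng.integers(0, len(rows)))]["sequence"]
        for _ in range(200):
            if template:
                letters = list(template)
                rng.shuffle(letters)
                pep = "".join(letters)
            else:
                pep_len = int(rng.integers(lo, hi + 1))
                pep = "".join(
                    "ACDEFGHIKLMNPQRSTVWY"[i]
                    for i in rng.integers(0, 20, size=pep_len)
                )
            if not _in_any_translation(pep):
                break
            template = None  # fall back to fully random draws
        else:
            raise RuntimeError("could not generate a verified decoy")
        rows.append({"peptide_id": f"pep_decoy_{k:04d}", "sequence": pep,
                     "is_true": False, "source_transcript": ""})
    return pd.DataFrame(
        rows, columns=["peptide_id", "sequence", "is_true", "source_transcript"]
    )


# ---------------------------------------------------------------------------
# Count matrices

CONDITIONS = ("ctrl", "miR_like", "miPEP_like")


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial count matrix over three conditions with planted
    differential-expression sets.

    Gene relative abundances are log-normal.  A-specific genes shift by
    +/- ``effect_logfc`` (log2) in miR_like only, B-specific in miPEP_like
    only, shared genes in both (same sign).  Counts are
    NB(mean = library size x relative abundance x fold change, dispersion
    = ``dispersion``).  Returns the matrix and a per-gene label table.
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for downstream dispersion estimation")
    rng = _rng(config.seed, 3)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base /= base.sum()

    n_a = int(round(n * config.frac_specific_A))
    n_b = int(round(n * config.frac_specific_B))
    n_s = int(round(n * config.frac_shared))
    perm = rng.permutation(n)
    groups = np.array(["none"] * n, dtype=object)
    groups[perm[:n_a]] = "A_specific"
    groups[perm[n_a : n_a + n_b]] = "B_specific"
    groups[perm[n_a + n_b : n_a + n_b + n_s]] = "shared"
    signs = rng.choice([-1.0, 1.0], size=n)

    fc = np.ones((n, 3))  # columns follow CONDITIONS order
    delta = 2.0 ** (signs * config.effect_logfc)
    fc[groups == "A_specific", 1] = delta[groups == "A_specific"]
    fc[groups == "B_specific", 2] = delta[groups == "B_specific"]
    fc[groups == "shared", 1] = delta[groups == "shared"]
    fc[groups == "shared", 2] = delta[groups == "shared"]

    phi = config.dispersion
    nb_n = 1.0 / phi
    cols, data, cond_labels = [], [], []
    for ci, cond in enumerate(CONDITIONS):
        for rep in range(config.n_reps):
            lib = rng.uniform(*config.lib_size_range)
            mu = lib * base * fc[:, ci]
            counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
            cols.append(f"{cond}_{rep + 1}")
            cond_labels.append(cond)
            data.append(counts)
    counts_df = pd.DataFrame(
        np.column_stack(data), index=gene_ids, columns=cols
    )
    cm = CountMatrix(counts_df, pd.Series(cond_labels, index=cols))
    labels = pd.DataFrame(
        {"gene_id": gene_ids, "group": groups,
         "sign": np.where(groups == "none", 0, signs).astype(int)}
    )
    return cm, labels


# ---------------------------------------------------------------------------
# Progeny and phenotypes

def simulate_progeny(
    scheme: CrossScheme,
    n: int,
    effect: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> dict[str, int]:
    """Multinomial progeny class counts under a cross scheme.

    ``effect`` maps class name to relative viability (1 = neutral); the
    Mendelian expected fractions are reweighted by viability and
    renormalized before drawing.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _rng(seed, 4)
    expected = expected_fractions(scheme)
    classes = sorted(expected)
    weights = np.array([
        float(expected[c]) * (effect.get(c, 1.0) if effect else 1.0)
        for c in classes
    ])
    total = weights.sum()
    if total <= 0:
        raise ValueError("all classes have zero viability")
    draws = rng.multinomial(n, weights / total)
    return dict(zip(classes, (int(d) for d in draws)))


def simulate_phenotypes(
    config: SimConfig,
    group_shifts: Optional[Mapping[str, float]] = None,
    heavy_tailed: bool = False,
) -> dict[str, np.ndarray]:
    """Grouped continuous measurements (wing-size style, arbitrary units).

    Each group is baseline 10 AU plus its shift (in units of
    ``phenotype_effect``); noise is Normal(0, phenotype_sd) or, when
    ``heavy_tailed``, scaled Student t with 3 df.
    """
    rng = _rng(config.seed, 5)
    if group_shifts is None:
        group_shifts = {"control": 0.0, "affected": -1.0}
    out = {}
    for group, shift in group_shifts.items():
        loc = 10.0 + shift * config.phenotype_effect
        if heavy_tailed:
            noise = rng.standard_t(df=3, size=config.phenotype_n) * config.phenotype_sd
        else:
            noise = rng.normal(0.0, config.phenotype_sd, size=config.phenotype_n)
        out[group] = loc + noise
    return out
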