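"""TMM, simplified NB testing, BH adjustment, set partitioning."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mipepscan.de_partition import (
    CountMatrix, DEResult, bh_adjust, call_de, nb_test, partition,
    row_standardize, run_de_pipeline, tmm_factors,
)
from mipepscan.synthio import SimConfig, simulate_counts


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


def tmm_oracle(counts, ref_col):
    """Independent trim-and-weight computation of TMM factors."""
    x = counts.to_numpy(float)
    lib = x.sum(axis=0)
    out = []
    for j in range(x.shape[1]):
        obs, ref = x[:, j], x[:, ref_col]
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.log2((obs / lib[j]) / (ref / lib[ref_col]))
            a = 0.5 * (np.log2(obs / lib[j]) + np.log2(ref / lib[ref_col]))
            w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref_col] - ref) / (
                lib[ref_col] * ref
            )
        ok = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[ok], a[ok], w[ok]
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            out.append(1.0)
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        out.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])))
    out = np.asarray(out)
    return out / np.exp(np.mean(np.log(out)))


def test_tmm_identical_libraries_give_unit_factors():
    counts = pd.DataFrame(np.tile([[10], [200], [35], [4]], (1, 4)))
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_pure_depth_change_gives_unit_factors():
    base = np.array([10, 200, 35, 4, 90, 55])
    counts = pd.DataFrame({"a": base, "b": 2 * base})
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_matches_independent_oracle(rng):
    counts = pd.DataFrame(rng.poisson(50, size=(20, 3)) + 1,
                          columns=["s1", "s2", "s3"])
    counts.iloc[:4, 2] *= 5  # composition shift
    f = tmm_factors(counts).to_numpy()
    x = counts.to_numpy(float)
    uq = np.quantile(x, 0.75, axis=0) / x.sum(axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    assert np.allclose(f, tmm_oracle(counts, ref), atol=1e-10)


def test_tmm_geometric_mean_one_and_permutation_equivariance(rng):
    counts = pd.DataFrame(rng.poisson(80, size=(100, 5)) + 1,
                          columns=list("abcde"))
    f = tmm_factors(counts)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)
    perm = ["c", "a", "e", "b", "d"]
    f2 = tmm_factors(counts[perm])
    assert np.allclose(f[perm].to_numpy(), f2.to_numpy())


def test_tmm_matches_edger_reference():
    """Cross-check against Bioconductor edgeR's calcNormFactors on a small
    matrix (independent reference implementation)."""
    rng = np.random.default_rng(5)
    x = rng.negative_binomial(10, 10 / (10 + rng.lognormal(4, 1, size=(200, 4))))
    x[:20, 1] *= 6
    counts = pd.DataFrame(x, columns=list("abcd"))
    f = tmm_factors(counts).to_numpy()
    script = textwrap.dedent("""
        suppressMessages(library(edgeR))
        x <- matrix(scan('stdin', quiet=TRUE), ncol=4, byrow=TRUE)
        d <- calcNormFactors(DGEList(counts=x), method='TMM')
        cat(sprintf('%.10f', d$samples$norm.factors), sep='\\n')
    """)
    proc = subprocess.run(
        ["Rscript", "-e", script],
        input="\n".join(" ".join(map(str, row)) for row in x),
        capture_output=True, text=True, check=True,
    )
    ref = np.array([float(v) for v in proc.stdout.split()])
    assert np.allclose(f, ref, atol=1e-6)


def test_tmm_rejects_all_zero_library():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="all-zero"):
        tmm_factors(counts)


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_equals_step_up_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 40))
        p = rng.uniform(size=n)
        if rng.random() < 0.3:
            p = np.round(p, 1)  # ties
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def _results(pairs, contrast="A_vs_ctrl"):
    return [DEResult(f"g{i}", contrast, lf, p) for i, (lf, p) in enumerate(pairs)]


def test_call_de_q_boundary_inclusive():
    called = call_de(_results([(1.0, 0.05)]), q_max=0.05)
    assert called["direction"].iloc[0] == "up"


def test_call_de_fc_boundary_strict():
    fc15 = np.log2(1.5)
    called = call_de(_results([(fc15, 0.001), (fc15 + 0.01, 0.001)]),
                     q_max=0.05, min_abs_fc=1.5)
    assert list(called["direction"]) == ["ns", "up"]
    # down-regulation with |FC| > 1.5 also passes
    called = call_de(_results([(-1.0, 0.001)]), q_max=0.05, min_abs_fc=1.5)
    assert called["direction"].iloc[0] == "down"


def test_call_de_empty():
    assert call_de([]).empty


def test_nb_test_all_zero_gene_convention():
    counts = pd.DataFrame(
        {"c1": [0, 5], "c2": [0, 9], "t1": [0, 4], "t2": [0, 7]},
        index=["gz", "g1"],
    )
    cm = CountMatrix(counts, pd.Series(["ctrl", "ctrl", "trt", "trt"],
                                       index=counts.columns))
    res = nb_test(cm, None, ("trt", "ctrl"))
    assert res[0].p_raw == 1.0 and res[0].logfc == 0.0


def test_nb_test_requires_replicates():
    counts = pd.DataFrame({"c1": [1], "c2": [2], "t1": [3]}, index=["g"])
    with pytest.raises(ValueError):
        CountMatrix(counts, pd.Series(["ctrl", "ctrl", "trt"], index=counts.columns))


def test_nb_null_type_one_error_calibrated():
    """Under the null the raw p<0.05 fraction stays within binomial 3 sigma."""
    cm, _ = simulate_counts(SimConfig(seed=11, n_genes=2000, effect_logfc=0.0))
    p = np.array([r.p_raw for r in nb_test(cm, tmm_factors(cm.counts),
                                           ("miR_like", "ctrl"))])
    sigma = np.sqrt(0.05 * 0.95 / p.size)
    assert abs((p < 0.05).mean() - 0.05) <= 3 * sigma


def test_nb_sensitivity_exceeds_frozen_bound():
    """Planted |log2FC|=1.5 at dispersion 0.1, 5 reps: sensitivity at
    q<=0.05 exceeds the pre-registered simulation bound of 0.9."""
    cm, labels = simulate_counts(SimConfig(seed=101))
    called = call_de(nb_test(cm, tmm_factors(cm.counts), ("miPEP_like", "ctrl")))
    reg = set(called.loc[called.direction != "ns", "gene_id"])
    planted = set(labels.loc[labels.group.isin(["B_specific", "shared"]), "gene_id"])
    assert len(reg & planted) / len(planted) >= 0.9


def test_null_false_discovery_proportion_controlled():
    fdps = []
    for seed in range(301, 306):
        cm, labels = simulate_counts(SimConfig(seed=seed))
        called = call_de(nb_test(cm, tmm_factors(cm.counts), ("miR_like", "ctrl")))
        reg = set(called.loc[called.direction != "ns", "gene_id"])
        true_a = set(labels.loc[labels.group.isin(["A_specific", "shared"]), "gene_id"])
        fdps.append(len(reg - true_a) / max(1, len(reg)))
    assert np.mean(fdps) <= 0.05 + 0.05  # Monte-Carlo tolerance


def _called(genes_up, genes_down, universe, contrast):
    rows = []
    for g in universe:
        d = "up" if g in genes_up else ("down" if g in genes_down else "ns")
        rows.append({"gene_id": g, "contrast": contrast, "logfc": 0.0,
                     "p_raw": 0.5, "q_bh": 0.5, "direction": d})
    return pd.DataFrame(rows)


def test_partition_disjoint_and_identical():
    uni = [f"g{i}" for i in range(10)]
    a = _called({"g0", "g1"}, set(), uni, "A")
    b = _called({"g5"}, {"g6"}, uni, "B")
    s = partition(a, b)
    assert (s.n_shared, s.pct_shared_of_b) == (0, 0.0)
    assert s.n_a_only + s.n_b_only + s.n_shared == 4
    same = partition(a, a.assign(contrast="B"))
    assert same.pct_shared_of_a == 100.0 and same.pct_shared_of_b == 100.0


def test_partition_universe_mismatch_errors():
    a = _called(set(), set(), ["g1"], "A")
    b = _called(set(), set(), ["g2"], "B")
    with pytest.raises(ValueError, match="universe"):
        partition(a, b)


def test_partition_direction_breakdown():
    uni = [f"g{i}" for i in range(6)]
    a = _called({"g0"}, {"g1"}, uni, "A")
    b = _called({"g0", "g2"}, set(), uni, "B")
    s = partition(a, b)
    assert s.directions["shared"] == {"up/up": 1}
    assert s.directions["A_only"] == {"down": 1}
    assert s.directions["B_only"] == {"up": 1}


def test_pipeline_recovers_planted_co_regulated_fraction():
    """End-to-end TMM->NB->BH->partition on a few planted simulations:
    recovered shared-of-B percentage close to the planted 24%."""
    vals = []
    for seed in (1, 2, 3, 4, 5):
        cm, _ = simulate_counts(SimConfig(seed=seed))
        _, _, summ = run_de_pipeline(cm, ("miR_like", "ctrl"), ("miPEP_like", "ctrl"))
        vals.append(summ.pct_shared_of_b)
    assert abs(np.mean(vals) - 24.0) <= 5.0


def test_row_standardize():
    m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    out = row_standardize(m)
    assert np.allclose(out.iloc[0], [-1, 0, 1])
    assert np.allclose(out.iloc[1], 0.0)


def test_row_standardize_random_matrix(rng):
    m = pd.DataFrame(rng.normal(size=(50, 10)))
    out = row_standardize(m).to_numpy()
    assert np.abs(out.mean(axis=1)).max() < 1e-10
    assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-10
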