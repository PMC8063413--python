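"""TMM normalization, simplified negative-binomial testing, BH-FDR, and
two-condition partitioning of regulated gene sets.

The testing framework is deliberately a documented, simplified NB pipeline:
per-gene moment dispersion estimates shrunk toward the common (all-gene)
estimate with a fixed weight, followed by a Wald test on the difference of
log normalized group means with NB-based variance.  It is calibrated by
simulation (null type-I error, planted-effect recovery), not by matching
any particular reference implementation gene-by-gene.

Counts are held in a :class:`CountMatrix`; conditions are free-form labels
(the canonical three-condition design is ctrl / miR_like / miPEP_like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample condition labels."""

    counts: pd.DataFrame           # index = gene ids, columns = sample ids
    conditions: pd.Series          # index = sample ids, values = condition labels

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            raise ValueError("every sample needs a condition label")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        vc = self.conditions.value_counts()
        if (vc < 2).any():
            raise ValueError(f"conditions with <2 replicates: {list(vc[vc < 2].index)}")

    def samples_for(self, condition: str) -> list[str]:
        return list(self.conditions[self.conditions == condition].index)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    contrast: str
    logfc: float           # log2 treated/ctrl
    p_raw: float
    q_bh: float = np.nan
    direction: str = "ns"  # up | down | ns


@dataclass
class PartitionSummary:
    """Three-way partition of two regulated gene sets with direction classes."""

    n_a_only: int
    n_b_only: int
    n_shared: int
    pct_shared_of_a: float
    pct_specific_of_a: float
    pct_shared_of_b: float
    pct_specific_of_b: float
    directions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_A_only": self.n_a_only,
            "n_B_only": self.n_b_only,
            "n_shared": self.n_shared,
            "pct_shared_of_A": self.pct_shared_of_a,
            "pct_specific_of_A": self.pct_specific_of_a,
            "pct_shared_of_B": self.pct_shared_of_b,
            "pct_specific_of_B": self.pct_specific_of_b,
            "directions": self.directions,
        }


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference library.

    M-values (log2 ratio of relative abundances) are trimmed 30% two-sided,
    A-values (mean log2 abundance) 5% two-sided; the kept M-values are
    averaged with inverse asymptotic-variance weights (delta method for a
    log binomial proportion).
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_expr_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    kept = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not kept.any():
        return 1.0
    f = np.sum(log_r[kept] / v[kept]) / np.sum(1.0 / v[kept])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference sample is the library whose upper-quartile relative
    abundance is closest to the across-sample mean.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >=2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero library")
    uq = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [_tmm_pair_factor(x[:, j], x[:, ref_idx]) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Simplified NB test

def _moment_dispersion(z: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene within-group moment estimate of the NB dispersion phi
    (Var = mu + phi mu^2), pooled across groups; negative estimates floor
    at 0."""
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    for idx in groups:
        zi = z[:, idx]
        n = zi.shape[1]
        m = zi.mean(axis=1)
        v = zi.var(axis=1, ddof=1)
        num += (n - 1) * (v - m)
        den += (n - 1) * m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.maximum(phi, 0.0)


def nb_test(
    cm: CountMatrix,
    factors: Optional[pd.Series],
    contrast: tuple[str, str],
    shrink_weight: float = 0.7,
    pseudo_mean: float = 0.5,
) -> list[DEResult]:
    """Wald test per gene for one (treated, ctrl) contrast.

    Counts are scaled by effective library size (library total x TMM
    factor).  Per-gene dispersions are moment estimates shrunk toward the
    common (all-gene mean over expressed genes) dispersion with weight
    ``shrink_weight`` on the common value.  The Wald statistic on the
    difference of natural-log normalized group means, with NB variance, is
    referred to the standard normal.  Genes with all-zero counts in both
    groups get p=1, logFC=0.
    """
    treated, ctrl = contrast
    if factors is None:
        factors = pd.Series(1.0, index=cm.counts.columns)
    cols = list(cm.counts.columns)
    s_t = [cols.index(s) for s in cm.samples_for(treated)]
    s_c = [cols.index(s) for s in cm.samples_for(ctrl)]
    if len(s_t) < 2 or len(s_c) < 2:
        raise ValueError("need >=2 replicates per group")

    y = cm.counts.to_numpy(dtype=float)
    eff_lib = y.sum(axis=0) * factors.reindex(cols).to_numpy()
    size = eff_lib / np.exp(np.mean(np.log(eff_lib)))   # size factors, geo-mean 1
    z = y / size                                        # normalized counts

    idx_t = np.asarray(s_t)
    idx_c = np.asarray(s_c)
    phi_gene = _moment_dispersion(z, [idx_t, idx_c])
    expressed = z[:, np.concatenate([idx_t, idx_c])].mean(axis=1) > 1
    phi_common = float(phi_gene[expressed].mean()) if expressed.any() else 0.0
    phi = shrink_weight * phi_common + (1.0 - shrink_weight) * phi_gene

    m_t = z[:, idx_t].mean(axis=1)
    m_c = z[:, idx_c].mean(axis=1)
    n_t, n_c = len(idx_t), len(idx_c)
    inv_s_t = np.mean(1.0 / size[idx_t])
    inv_s_c = np.mean(1.0 / size[idx_c])

    logfc = np.log2(m_t + pseudo_mean) - np.log2(m_c + pseudo_mean)
    # Var(log mean) by the delta method; Var(z_i) = mu/s_i + phi mu^2
    var_t = (m_t * inv_s_t + phi * m_t ** 2) / n_t
    var_c = (m_c * inv_s_c + phi * m_c ** 2) / n_c
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            var_t / (m_t + pseudo_mean) ** 2 + var_c / (m_c + pseudo_mean) ** 2
        )
        wald = (np.log(m_t + pseudo_mean) - np.log(m_c + pseudo_mean)) / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    both_zero = (m_t == 0) & (m_c == 0)
    p = np.where(both_zero | ~np.isfinite(p), 1.0, p)
    logfc = np.where(both_zero, 0.0, logfc)

    label = f"{treated}_vs_{ctrl}"
    return [
        DEResult(gene_id=g, contrast=label, logfc=float(lf), p_raw=float(pv))
        for g, lf, pv in zip(cm.counts.index, logfc, p)
    ]


# ---------------------------------------------------------------------------
# Multiple testing, calling and partitioning

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: Sequence[DEResult],
    q_max: float = 0.05,
    min_abs_fc: Optional[float] = None,
) -> pd.DataFrame:
    """Attach q-values and direction calls to one contrast's results.

    A gene is regulated iff q <= q_max (inclusive) and, when ``min_abs_fc``
    is set, its linear fold change satisfies |FC| > min_abs_fc (strict).
    Direction is the sign of logFC.
    """
    if not results:
        return pd.DataFrame(
            columns=["gene_id", "contrast", "logfc", "p_raw", "q_bh", "direction"]
        )
    contrasts = {r.contrast for r in results}
    if len(contrasts) != 1:
        raise ValueError("call_de expects results from a single contrast")
    q = bh_adjust([r.p_raw for r in results])
    rows = []
    for r, qv in zip(results, q):
        sig = qv <= q_max
        if sig and min_abs_fc is not None:
            sig = 2.0 ** abs(r.logfc) > min_abs_fc
        direction = "ns"
        if sig:
            direction = "up" if r.logfc > 0 else "down"
        rows.append(
            {"gene_id": r.gene_id, "contrast": r.contrast, "logfc": r.logfc,
             "p_raw": r.p_raw, "q_bh": float(qv), "direction": direction}
        )
    return pd.DataFrame(rows)


def regulated_sets(called: pd.DataFrame) -> dict[str, set[str]]:
    """Gene-id sets by direction from a call_de table."""
    up = set(called.loc[called.direction == "up", "gene_id"])
    down = set(called.loc[called.direction == "down", "gene_id"])
    return {"up": up, "down": down, "all": up | down}


def partition(
    called_a: pd.DataFrame, called_b: pd.DataFrame
) -> PartitionSummary:
    """Partition two conditions' regulated genes into A-only / B-only /
    shared, with direction breakdown; percentages are relative to each
    condition's regulated set.  The two call tables must share a gene
    universe."""
    if set(called_a.gene_id) != set(called_b.gene_id):
        raise ValueError("gene universes differ between the two contrasts")
    sets_a = regulated_sets(called_a)
    sets_b = regulated_sets(called_b)
    a, b = sets_a["all"], sets_b["all"]
    shared = a & b
    a_only = a - b
    b_only = b - a

    def _pct(part: int, whole: int) -> float:
        return 100.0 * part / whole if whole else float("nan")

    dir_a = called_a.set_index("gene_id")["direction"]
    dir_b = called_b.set_index("gene_id")["direction"]
    directions = {
        "A_only": dict(pd.Series([dir_a[g] for g in a_only]).value_counts())
        if a_only else {},
        "B_only": dict(pd.Series([dir_b[g] for g in b_only]).value_counts())
        if b_only else {},
        "shared": dict(
            pd.Series([f"{dir_a[g]}/{dir_b[g]}" for g in shared]).value_counts()
        )
        if shared else {},
    }
    directions = {
        k: {kk: int(vv) for kk, vv in v.items()} for k, v in directions.items()
    }
    return PartitionSummary(
        n_a_only=len(a_only),
        n_b_only=len(b_only),
        n_shared=len(shared),
        pct_shared_of_a=_pct(len(shared), len(a)),
        pct_specific_of_a=_pct(len(a_only), len(a)),
        pct_shared_of_b=_pct(len(shared), len(b)),
        pct_specific_of_b=_pct(len(b_only), len(b)),
        directions=directions,
    )


def row_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0 and sample (ddof=1) sd 1; constant
    rows map to all zeros (heatmap convention)."""
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def run_de_pipeline(
    cm: CountMatrix,
    contrast_a: tuple[str, str],
    contrast_b: tuple[str, str],
    q_max: float = 0.05,
    min_abs_fc: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PartitionSummary]:
    """TMM -> NB test -> BH -> call -> partition for two contrasts against
    a shared control.  Returns (calls_A, calls_B, partition summary)."""
    factors = tmm_factors(cm.counts)
    res_a = nb_test(cm, factors, contrast_a)
    res_b = nb_test(cm, factors, contrast_b)
    called_a = call_de(res_a, q_max=q_max, min_abs_fc=min_abs_fc)
    called_b = call_de(res_b, q_max=q_max, min_abs_fc=min_abs_fc)
    return called_a, called_b, partition(called_a, called_b)
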