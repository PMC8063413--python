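"""Mendelian cross expectations with balancer lethality, goodness-of-fit
tests on progeny counts, and the measurement-statistics decision battery.

A :class:`CrossScheme` holds both parents' genotypes as per-locus unordered
allele pairs, a set of lethal genotype patterns (balancer homozygotes such
as CyO/CyO are the canonical case), and a mapping from progeny genotypes to
named phenotypic classes.  Expected class fractions come from gamete
enumeration with equal segregation and independent assortment, dropping
lethal genotypes and renormalizing — e.g. a construct/CyO intercross yields
1/3 homozygotes and 2/3 CyO among viable offspring.

The phenotype battery mirrors the standard decision tree: D'Agostino-
Pearson normality per group, then either ANOVA (+ Bartlett equal-variance
gate, Bonferroni pairwise) or Kruskal-Wallis (+ pairwise Mann-Whitney,
Bonferroni); two groups go straight to a t-test or Mann-Whitney.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

Genotype = tuple[tuple[str, str], ...]   # per-locus sorted allele pairs


def _norm_pair(pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class CrossScheme:
    """Two parental genotypes, lethal genotype patterns, and a class map.

    ``parent1``/``parent2``: list of per-locus allele pairs, same locus
    order for both parents.  ``lethal``: genotype patterns (per-locus pairs,
    or None for "any" at a locus) that are inviable.  ``class_map``: ordered
    (pattern, class-name) list; the first matching pattern names the class,
    unmatched genotypes fall back to a canonical string form.
    """

    parent1: Sequence[Sequence[str]]
    parent2: Sequence[Sequence[str]]
    lethal: Sequence[Sequence[Optional[Sequence[str]]]] = field(default_factory=list)
    class_map: Sequence[tuple[Sequence[Optional[Sequence[str]]], str]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if len(self.parent1) != len(self.parent2):
            raise ValueError("parents must have the same number of loci")
        self.parent1 = [_norm_pair(p) for p in self.parent1]
        self.parent2 = [_norm_pair(p) for p in self.parent2]


def genotype_label(gt: Genotype) -> str:
    return ";".join("/".join(pair) for pair in gt)


def _pattern_matches(
    pattern: Sequence[Optional[Sequence[str]]], gt: Genotype
) -> bool:
    if len(pattern) != len(gt):
        return False
    for pat, pair in zip(pattern, gt):
        if pat is None:
            continue
        if _norm_pair(pat) != pair:
            return False
    return True


def progeny_distribution(scheme: CrossScheme) -> dict[Genotype, Fraction]:
    """Exact genotype distribution before lethality (Punnett enumeration).

    Gametes get one allele per locus with probability 1/2 each, assorting
    independently; progeny probabilities are exact Fractions.
    """
    n_loci = len(scheme.parent1)
    gametes1 = list(itertools.product(*scheme.parent1))
    gametes2 = list(itertools.product(*scheme.parent2))
    dist: dict[Genotype, Fraction] = {}
    w = Fraction(1, len(gametes1) * len(gametes2))
    for g1 in gametes1:
        for g2 in gametes2:
            gt = tuple(_norm_pair((g1[i], g2[i])) for i in range(n_loci))
            dist[gt] = dist.get(gt, Fraction(0)) + w
    return dist


def expected_fractions(scheme: CrossScheme) -> dict[str, Fraction]:
    """Expected viable progeny class fractions.

    Lethal genotypes are dropped and the remainder renormalized; genotypes
    are then aggregated by the scheme's class map.  Fractions are exact
    (e.g. Fraction(1, 3) for homozygotes in a balancer intercross).
    """
    dist = progeny_distribution(scheme)
    viable = {
        gt: p
        for gt, p in dist.items()
        if not any(_pattern_matches(pat, gt) for pat in scheme.lethal)
    }
    total = sum(viable.values(), Fraction(0))
    if total == 0:
        raise ValueError("all progeny genotypes are lethal")
    out: dict[str, Fraction] = {}
    for gt, p in viable.items():
        name = genotype_label(gt)
        for pattern, cls in scheme.class_map:
            if _pattern_matches(pattern, gt):
                name = cls
                break
        out[name] = out.get(name, Fraction(0)) + p / total
    return out


# ---------------------------------------------------------------------------
# Goodness of fit on observed progeny classes

def _exact_multinomial_p(observed: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p: total probability of outcomes
    no more likely than the observed one."""
    n = int(observed.sum())
    k = len(probs)
    p_obs = stats.multinomial.pmf(observed, n, probs)
    total = 0.0
    for combo in itertools.product(range(n + 1), repeat=k - 1):
        if sum(combo) > n:
            continue
        outcome = np.array(list(combo) + [n - sum(combo)])
        p = stats.multinomial.pmf(outcome, n, probs)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, float(total))


def deviation_test(
    observed: Mapping[str, int], expected: Mapping[str, float]
) -> dict:
    """Test observed class counts against expected fractions.

    Two classes: exact two-sided binomial.  More classes: chi-square
    goodness of fit, replaced by the exact multinomial test when any
    expected count falls below 5 and the enumeration is small (n <= 60,
    <= 4 classes).  Returns a dict with the method, statistic and p-value.
    """
    classes = list(expected)
    obs = np.array([int(observed.get(c, 0)) for c in classes])
    exp_frac = np.array([float(expected[c]) for c in classes])
    n = int(obs.sum())
    if n <= 0:
        raise ValueError("total observed count must be > 0")
    if not math.isclose(exp_frac.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected fractions must sum to 1")
    if np.any((exp_frac == 0) & (obs > 0)):
        raise ValueError("nonzero observation in a class with expected fraction 0")

    if len(classes) == 2:
        res = stats.binomtest(int(obs[0]), n, exp_frac[0], alternative="two-sided")
        return {"method": "exact_binomial", "statistic": float(obs[0]),
                "p_value": float(res.pvalue), "n": n}
    exp_counts = n * exp_frac
    if np.any(exp_counts < 5) and n <= 60 and len(classes) <= 4:
        p = _exact_multinomial_p(obs, exp_frac)
        return {"method": "exact_multinomial", "statistic": float("nan"),
                "p_value": p, "n": n}
    chi2, p = stats.chisquare(obs, exp_counts)
    return {"method": "chi_square", "statistic": float(chi2),
            "p_value": float(p), "n": n}


# ---------------------------------------------------------------------------
# Measurement battery

def summarize_groups(data: Mapping[str, Sequence[float]]) -> list[dict]:
    """Mean, s.e.m. (sample sd / sqrt(n)) and n per group; a single value
    gives an undefined (NaN) s.e.m."""
    rows = []
    for group, values in data.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {group!r}")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append({"group": group, "n": int(v.size),
                     "mean": float(v.mean()), "sem": sem})
    return rows


def stats_battery(data: Mapping[str, Sequence[float]], alpha: float = 0.05) -> dict:
    """Run the normality-gated decision battery on grouped measurements.

    D'Agostino-Pearson normality per group (needs n >= 8; smaller groups
    force the nonparametric branch, logged in the report).  All groups
    Gaussian and Bartlett-homoscedastic -> one-way ANOVA with Bonferroni
    pairwise t-tests; otherwise Kruskal-Wallis with Bonferroni pairwise
    Mann-Whitney.  With exactly two groups the global test is the pairwise
    one (t-test if Gaussian, Mann-Whitney otherwise).

    Returns a report dict with the branch taken, every intermediate
    p-value, the global p, and pairwise adjusted p-values.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in data.items()}
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has n < 3")

    report: dict = {"alpha": alpha, "normality": {}, "notes": []}
    normal_ok = True
    for g, v in groups.items():
        if v.size < 8:
            report["normality"][g] = None
            report["notes"].append(
                f"group {g}: n={v.size} < 8, normality untestable; "
                "nonparametric branch forced"
            )
            normal_ok = False
            continue
        stat, p = stats.normaltest(v)
        report["normality"][g] = float(p)
        if p < alpha:
            normal_ok = False

    names = list(groups)
    values = [groups[g] for g in names]
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)

    if normal_ok:
        bart_stat, bart_p = stats.bartlett(*values)
        report["bartlett_p"] = float(bart_p)
        normal_ok = bart_p >= alpha

    if normal_ok:
        if len(names) == 2:
            report["branch"] = "t_test"
            stat, p = stats.ttest_ind(values[0], values[1])
        else:
            report["branch"] = "anova_bonferroni"
            stat, p = stats.f_oneway(*values)
        pairwise_raw = [
            float(stats.ttest_ind(groups[a], groups[b]).pvalue) for a, b in pairs
        ]
    else:
        if len(names) == 2:
            report["branch"] = "mann_whitney"
            stat, p = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
        else:
            report["branch"] = "kruskal_mannwhitney_bonferroni"
            stat, p = stats.kruskal(*values)
        pairwise_raw = [
            float(
                stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            )
            for a, b in pairs
        ]

    report["global_statistic"] = float(stat)
    report["global_p"] = float(p)
    report["pairwise"] = [
        {"group_a": a, "group_b": b, "p_raw": pr,
         "p_adjusted": float(min(1.0, pr * m))}
        for (a, b), pr in zip(pairs, pairwise_raw)
    ]
    report["group_summary"] = summarize_groups(data)
    return report


# ---------------------------------------------------------------------------
# Canonical schemes from the study's crosses

def balancer_intercross(construct: str = "KI", balancer: str = "CyO") -> CrossScheme:
    """construct/CyO x construct/CyO with CyO/CyO inviable: expected 1/3
    homozygotes, 2/3 balancer-carrying among viable progeny."""
    return CrossScheme(
        parent1=[(construct, balancer)],
        parent2=[(construct, balancer)],
        lethal=[[(balancer, balancer)]],
        class_map=[
            ([(construct, construct)], f"{construct}/{construct}"),
            ([(construct, balancer)], f"{construct}/{balancer}"),
        ],
    )


def driver_responder_cross(
    driver: str = "GAL4", balancer: str = "Balancer", responder: str = "UAS"
) -> CrossScheme:
    """Balanced GAL4 driver x homozygous UAS responder: 50% driver>UAS,
    50% balancer;UAS under neutral segregation."""
    return CrossScheme(
        parent1=[(driver, balancer)],
        parent2=[(responder, responder)],
        lethal=[],
        class_map=[
            ([(driver, responder)], "driver>UAS"),
            ([(balancer, responder)], "Bal;UAS"),
        ],
    )
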