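"""Effect sizes, random-effects meta-analysis, and overlap statistics.

Implements Cohen's d with its large-sample variance, random-effects
pooling of standardized mean differences with the Sidik-Jonkman two-step
estimator of between-study variance, Benjamini-Hochberg adjustment with
an explicit denominator, the random-signature permutation null (pooled
effects of random k-microRNA combinations), rank-rank hypergeometric
overlap maps for two ranked lists, and hypergeometric gene-set overlap
with fold enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signature import EigenScore, compare_groups, eigen_expression

__all__ = [
    "MetaStudy",
    "MetaResult",
    "RRHOResult",
    "OverlapResult",
    "cohens_d",
    "pool_random_effects",
    "bh_adjust",
    "random_signature_null",
    "rrho_map",
    "geneset_overlap",
]


@dataclass(frozen=True)
class MetaStudy:
    """One study's standardized effect: d, its variance, group sizes."""

    label: str
    d: float
    v: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("effect variance must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass(frozen=True)
class MetaResult:
    """Pooled SMD with normal 95% CI, Z, two-sided p, tau^2 and k."""

    smd: float
    ci_lower: float
    ci_upper: float
    se: float
    z: float
    p: float
    tau2: float
    k: int


def cohens_d(group1: Sequence[float], group2: Sequence[float],
             label: str = "", hedges: bool = False) -> MetaStudy:
    """Cohen's d = (mean1 - mean2) / pooled SD, with sampling variance.

    The pooled SD uses unbiased group variances. The variance of d is
    (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)). ``hedges=True`` applies the
    small-sample correction factor J = 1 - 3/(4*df - 1) (off by default:
    Cohen's d is the effect measure reported by this framework).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 values")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("pooled SD is zero")
    d = (g1.mean() - g2.mean()) / math.sqrt(sp2)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    v = (n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * (n1 + n2))
    return MetaStudy(label=label, d=float(d), v=float(v), n1=n1, n2=n2)


def _tau2_sidik_jonkman(d: np.ndarray, v: np.ndarray) -> float:
    """Two-step Sidik-Jonkman estimate of between-study variance.

    Initial tau0^2 is the unweighted variance of the effects (divisor k);
    weights 1/(v_i/tau0^2 + 1) then re-estimate tau^2 around the weighted
    mean with divisor k - 1.
    """
    k = len(d)
    if k < 2:
        return 0.0
    tau0 = float(((d - d.mean()) ** 2).sum() / k)
    if tau0 <= 0:
        return 0.0
    r = v / tau0
    w = 1.0 / (r + 1.0)
    d_hat = float((w * d).sum() / w.sum())
    return float((w * (d - d_hat) ** 2).sum() / (k - 1))


def pool_random_effects(studies: Sequence[MetaStudy],
                        tau2: float | None = None) -> MetaResult:
    """Random-effects pooled SMD with Sidik-Jonkman tau^2.

    Study weights are 1/(v_i + tau^2); the CI is the normal-approximation
    95% interval and p is two-sided from Z = pooled / SE. A single study
    is passed through (tau^2 = 0). Passing ``tau2`` overrides the
    Sidik-Jonkman estimate (``tau2=0`` recovers fixed-effect
    inverse-variance pooling).
    """
    if not studies:
        raise ValueError("no studies to pool")
    d = np.array([s.d for s in studies], dtype=float)
    v = np.array([s.v for s in studies], dtype=float)
    k = len(studies)
    if tau2 is None:
        tau2 = _tau2_sidik_jonkman(d, v)
    elif tau2 < 0:
        raise ValueError("tau2 override must be non-negative")
    w = 1.0 / (v + tau2)
    pooled = float((w * d).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return MetaResult(smd=pooled, ci_lower=pooled - half, ci_upper=pooled + half,
                      se=se, z=float(z), p=p, tau2=float(tau2), k=k)


def bh_adjust(p: Sequence[float], n: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with explicit denominator.

    ``n`` defaults to the list length but may be larger (as when 1,000
    random combinations define the family while fewer p-values are
    adjusted); adjusted p_(i) = min over j >= i of p_(j) * n / j, capped
    at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if n is None:
        n = m
    if n < m:
        raise ValueError("n must be >= number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def random_signature_null(expr_by_dataset: Sequence[tuple[pd.DataFrame, pd.Series]],
                          candidate_pool: Sequence[str],
                          k: int = 3,
                          n_combos: int = 1000,
                          seed: int = 0,
                          focal_signature: Sequence[str] | None = None,
                          ) -> tuple[pd.DataFrame, float | None]:
    """Permutation null over random k-microRNA combinations.

    For each of ``n_combos`` seeded random k-subsets of ``candidate_pool``
    (drawn without replacement within a combo), the combo's eigen
    expression is computed in every dataset, Cohen's d contrasts the two
    groups, and the per-dataset effects are pooled by random-effects
    meta-analysis. Pooled p-values are BH-adjusted over the ``n_combos``
    family. If a ``focal_signature`` is given, its own pooled |SMD| is
    located on the null distribution and its percentile returned.

    Returns ``(table, focal_percentile)`` where the table has one row per
    combo (combo members, pooled SMD, Z, p, p_adjusted).
    """
    pool = list(candidate_pool)
    if len(pool) < k:
        raise ValueError("candidate pool smaller than combination size")
    for i, (expr, groups) in enumerate(expr_by_dataset):
        missing = [m for m in pool if m not in expr.index]
        if missing:
            raise KeyError(f"dataset {i}: pool members missing: {missing}")

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_combos):
        combo = tuple(rng.choice(pool, size=k, replace=False))
        res = _pooled_effect_of_set(expr_by_dataset, combo)
        rows.append({"combo": combo, "smd": res.smd, "z": res.z, "p": res.p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p"].to_numpy(), n=n_combos)

    percentile = None
    if focal_signature is not None:
        focal = _pooled_effect_of_set(expr_by_dataset, tuple(focal_signature))
        percentile = float(
            100.0 * (np.abs(table["smd"].to_numpy()) <= abs(focal.smd)).mean())
        table.attrs["focal_smd"] = focal.smd
        table.attrs["focal_p"] = focal.p
    return table, percentile


def _pooled_effect_of_set(expr_by_dataset, members) -> MetaResult:
    studies = []
    for i, (expr, groups) in enumerate(expr_by_dataset):
        es = eigen_expression(expr, list(members))
        g = pd.Series(groups).loc[es.scores.index]
        levels = pd.unique(g)
        a = es.scores[g == levels[0]].to_numpy()
        b = es.scores[g == levels[1]].to_numpy()
        studies.append(cohens_d(a, b, label=f"dataset-{i}"))
    return pool_random_effects(studies)


@dataclass
class RRHOResult:
    """Rank-rank hypergeometric overlap map.

    ``neglog10_p[i, j]`` is the -log10 one-sided hypergeometric enrichment
    p for the overlap of the top (i+1)*step of list 1 with the top
    (j+1)*step of list 2; ``neglog10_p_adjusted`` is its BH-adjusted twin
    (adjusted jointly over all cells). ``overlap`` holds the raw counts.
    """

    step: int
    thresholds: np.ndarray
    overlap: np.ndarray
    neglog10_p: np.ndarray
    neglog10_p_adjusted: np.ndarray


def rrho_map(rank1: Sequence[str], rank2: Sequence[str],
             step: int = 10) -> RRHOResult:
    """Rank-rank hypergeometric overlap of two rankings of one universe.

    Overlaps are counted at every ``step``-th rank threshold pair and
    tested for enrichment with the one-sided hypergeometric tail
    P(X >= observed).
    """
    r1, r2 = list(rank1), list(rank2)
    if set(r1) != set(r2) or len(set(r1)) != len(r1) or len(set(r2)) != len(r2):
        diff = set(r1) ^ set(r2)
        raise ValueError(f"rankings must permute the same universe; "
                         f"symmetric difference: {sorted(diff)}")
    n = len(r1)
    n_steps = n // step
    if n_steps < 1:
        raise ValueError("step larger than the universe")
    thresholds = np.arange(1, n_steps + 1) * step
    pos2 = {item: i for i, item in enumerate(r2)}
    ranks_in_2 = np.array([pos2[item] for item in r1])

    overlap = np.empty((n_steps, n_steps), dtype=int)
    pmat = np.empty((n_steps, n_steps))
    for i, ti in enumerate(thresholds):
        in_top1 = ranks_in_2[:ti]
        for j, tj in enumerate(thresholds):
            ov = int((in_top1 < tj).sum())
            overlap[i, j] = ov
            pmat[i, j] = stats.hypergeom.sf(ov - 1, n, tj, ti)
    adj = bh_adjust(pmat.ravel()).reshape(pmat.shape)
    tiny = np.finfo(float).tiny
    return RRHOResult(step=step, thresholds=thresholds, overlap=overlap,
                      neglog10_p=-np.log10(np.maximum(pmat, tiny)),
                      neglog10_p_adjusted=-np.log10(np.maximum(adj, tiny)))


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two sets within a universe."""

    observed: int
    expected: float
    fold_enrichment: float
    p: float

    def significant(self, fold_cut: float = 1.5, alpha: float = 0.05,
                    p_adjusted: float | None = None) -> bool:
        """The reporting rule used for target-set overlaps:
        fold enrichment > ``fold_cut`` and (adjusted) p < ``alpha``."""
        p = self.p if p_adjusted is None else p_adjusted
        return self.fold_enrichment > fold_cut and p < alpha


def geneset_overlap(set_a: Sequence[str], set_b: Sequence[str],
                    universe: Sequence[str]) -> OverlapResult:
    """Hypergeometric enrichment of |A intersect B| against chance.

    Expected overlap under independence is |A||B|/|U|; fold enrichment is
    observed / expected; p is the upper tail P(X >= observed).
    """
    u = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        outside = sorted((a | b) - u)
        raise ValueError(f"set elements outside universe: {outside}")
    observed = len(a & b)
    expected = len(a) * len(b) / len(u)
    fold = observed / expected if expected > 0 else math.nan
    p = float(stats.hypergeom.sf(observed - 1, len(u), len(a), len(b)))
    return OverlapResult(observed=observed, expected=expected,
                         fold_enrichment=fold, p=p)
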