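"""Eigen-expression scoring of a microRNA set in count data.

The pipeline order is fixed: low-count filtering, counts-per-million
log2 normalization, optional covariate residualization, sample-quality
outlier removal, then SVD of the z-scored signature submatrix. The
per-sample "eigen expression" is the leading right-singular vector scaled
by the leading singular value — the module-eigengene convention — with
the sign chosen so the score correlates positively with the set's mean
standardized expression. Group comparison (rank-sum), phenotype
correlation (Pearson) and sample stratification (k-means elbow + complete
linkage) operate on that score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.cluster import KMeans

__all__ = [
    "EigenScore",
    "filter_features",
    "normalize_log2",
    "regress_out_covariates",
    "sample_quality_z",
    "drop_outliers",
    "eigen_expression",
    "compare_groups",
    "correlate_phenotype",
    "cluster_scores",
]


@dataclass
class EigenScore:
    """Per-sample signature expression summary.

    ``scores`` is indexed by sample; ``variance_explained`` is the share
    of the set's variance carried by the leading singular component;
    ``sign_flipped`` records whether the default sign convention required
    flipping the raw SVD output.
    """

    scores: pd.Series
    variance_explained: float
    sign_flipped: bool
    dropped_samples: tuple[str, ...] = ()


def filter_features(counts: pd.DataFrame, min_reads: int,
                    min_fraction: float) -> pd.DataFrame:
    """Keep features with >= ``min_reads`` in >= ceil(min_fraction * n) samples.

    The default analysis filters (5 reads in 50% of samples for
    co-expression work; 100 reads in 50% for differential analysis) are
    instances of this rule.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    need = math.ceil(min_fraction * counts.shape[1])
    keep = (counts >= min_reads).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("filter removed every feature")
    return counts.loc[keep]


def normalize_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(1 + CPM): library-size normalization with pseudocount 1."""
    if counts.attrs.get("normalized"):
        raise ValueError("matrix is already normalized")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    expr = np.log2(1.0 + counts / libsize * 1e6)
    expr.attrs["normalized"] = True
    return expr


def regress_out_covariates(expr: pd.DataFrame, meta: pd.DataFrame,
                           covariate_names: list[str]) -> pd.DataFrame:
    """Per-feature OLS on the covariates; returns residual + feature mean.

    Categorical covariates are dummy-coded (first level dropped). A
    rank-deficient design aborts with the offending columns named.
    """
    missing = [c for c in covariate_names if c not in meta.columns]
    if missing:
        raise KeyError(f"covariates not in metadata: {missing}")
    meta = meta.loc[expr.columns]
    design_parts = [pd.Series(1.0, index=meta.index, name="intercept")]
    for c in covariate_names:
        col = meta[c]
        if pd.api.types.is_numeric_dtype(col):
            design_parts.append(col.astype(float))
        else:
            design_parts.append(pd.get_dummies(col, prefix=c, drop_first=True,
                                               dtype=float))
    X = pd.concat(design_parts, axis=1)
    Xm = X.to_numpy()
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify collinear columns via pivoted QR
        _, r = np.linalg.qr(Xm)
        bad = [X.columns[j] for j in range(Xm.shape[1])
               if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = expr.to_numpy().T  # samples x features
    beta, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ beta
    out = pd.DataFrame(resid.T + expr.mean(axis=1).to_numpy()[:, None],
                       index=expr.index, columns=expr.columns)
    out.attrs.update(expr.attrs)
    out.attrs["covariate_adjusted"] = True
    return out


def sample_quality_z(expr: pd.DataFrame) -> pd.Series:
    """Quality Z per sample: standardized mean inter-sample correlation.

    Each sample's mean Pearson correlation to all other samples
    (its network connectivity) is z-scored across samples. Atypical
    samples get extreme Z.
    """
    n = expr.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    corr = np.corrcoef(expr.to_numpy(), rowvar=False)
    np.fill_diagonal(corr, np.nan)
    conn = np.nanmean(corr, axis=1)
    sd = conn.std()
    if sd == 0 or not np.isfinite(sd):
        return pd.Series(0.0, index=expr.columns)
    return pd.Series((conn - conn.mean()) / sd, index=expr.columns)


def drop_outliers(expr: pd.DataFrame, threshold: float = 2.5) -> pd.DataFrame:
    """Remove samples with quality |Z| > ``threshold`` (single pass)."""
    if expr.shape[1] < 4:
        warnings.warn("fewer than 4 samples; outlier removal skipped")
        return expr
    z = sample_quality_z(expr)
    keep = z.abs() <= threshold
    out = expr.loc[:, keep]
    out.attrs.update(expr.attrs)
    return out


def eigen_expression(expr: pd.DataFrame, feature_set: list[str],
                     zscore_rows: bool = True,
                     drop_score_outliers: bool = False,
                     outlier_z: float = 2.5) -> EigenScore:
    """Leading-component summary of a feature set's expression.

    The set's rows are z-scored (configurable to centering only), the
    resulting set x sample matrix is decomposed by SVD, and each sample's
    score is the first right-singular vector scaled by the first singular
    value. Variance explained is sigma_1^2 / sum(sigma_i^2). With
    ``drop_score_outliers`` the score itself is screened at |Z| > 2.5 and
    recomputed once on the surviving samples.
    """
    missing = [f for f in feature_set if f not in expr.index]
    if missing:
        raise KeyError(f"signature features missing from matrix: {missing}")
    sub = expr.loc[list(feature_set)].astype(float)
    sd = sub.std(axis=1, ddof=0)
    dead = sd[sd == 0]
    if len(dead):
        warnings.warn(f"zero-variance signature features excluded: {list(dead.index)}")
        sub = sub.drop(index=dead.index)
    if sub.shape[0] < 2:
        raise ValueError("need >= 2 signature features with variance")
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")

    def _solve(mat: pd.DataFrame) -> tuple[pd.Series, float, bool]:
        z = mat.sub(mat.mean(axis=1), axis=0)
        if zscore_rows:
            z = z.div(z.std(axis=1, ddof=0), axis=0)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        score = s[0] * vt[0]
        ve = float(s[0] ** 2 / (s ** 2).sum())
        mean_z = z.mean(axis=0).to_numpy()
        flip = False
        c = np.corrcoef(score, mean_z)[0, 1]
        if np.isfinite(c) and c < 0:
            score = -score
            flip = True
        return pd.Series(score, index=mat.columns), ve, flip

    scores, ve, flip = _solve(sub)
    dropped: tuple[str, ...] = ()
    if drop_score_outliers and len(scores) >= 4:
        z = (scores - scores.mean()) / scores.std(ddof=0)
        keep = z.abs() <= outlier_z
        if not keep.all():
            dropped = tuple(scores.index[~keep])
            scores, ve, flip = _solve(sub.loc[:, keep])
    return EigenScore(scores=scores, variance_explained=ve,
                      sign_flipped=flip, dropped_samples=dropped)


def compare_groups(score: EigenScore | pd.Series,
                   groups: pd.Series) -> tuple[float, float]:
    """Unpaired two-sided Wilcoxon rank-sum test between two groups.

    Returns ``(W, p)`` where W is the rank-sum of the first group.
    The p-value is exact (full enumeration) when the combined n is <= 20
    and there are no ties, otherwise a tie-corrected normal approximation.
    """
    s = score.scores if isinstance(score, EigenScore) else score
    groups = pd.Series(groups).loc[s.index] if hasattr(groups, "loc") else pd.Series(
        list(groups), index=s.index)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    a = s[groups == levels[0]].to_numpy()
    b = s[groups == levels[1]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(stats.rankdata(pooled)[: len(a)].sum())
    return w, float(res.pvalue)


def correlate_phenotype(score: EigenScore | pd.Series,
                        phenotype: pd.Series) -> tuple[float, float]:
    """Pearson correlation of the eigen score with a phenotype."""
    s = score.scores if isinstance(score, EigenScore) else score
    ph = phenotype.loc[s.index] if hasattr(phenotype, "loc") else pd.Series(
        list(phenotype), index=s.index)
    if len(s) < 3:
        raise ValueError("need >= 3 paired values")
    if s.std(ddof=0) == 0 or ph.std(ddof=0) == 0:
        raise ValueError("zero variance in score or phenotype")
    r, p = stats.pearsonr(s.to_numpy(), ph.to_numpy(dtype=float))
    return float(r), float(p)


def _elbow_from_wss(wss: Sequence[float]) -> int:
    """Elbow of a WSS curve over k = 1..k_max: the k with the largest
    second difference WSS[k-1] - 2*WSS[k] + WSS[k+1]; ties break toward
    smaller k. A two-point curve can only elbow at k = 2."""
    k_max = len(wss)
    if k_max < 2:
        return 1
    if k_max == 2:
        return 2
    second = {k: wss[k - 2] - 2 * wss[k - 1] + wss[k] for k in range(2, k_max)}
    return max(sorted(second), key=lambda k: (second[k], -k))


def cluster_scores(score: EigenScore | pd.Series, k_max: int,
                   seed: int = 0) -> tuple[int, pd.Series, list[str]]:
    """Stratify samples on the eigen score: elbow k-means + complete linkage.

    The within-cluster sum of squares (WSS) is computed for k = 1..k_max
    with seeded k-means (25 restarts) on the scaled score; the chosen k
    maximizes the second difference of the WSS curve (ties broken toward
    smaller k; a flat curve yields k = 1). Assignments come from cutting a
    complete-linkage dendrogram on Euclidean distances at the chosen k.

    Returns ``(k, assignments, dendrogram_leaf_order)``.
    """
    s = score.scores if isinstance(score, EigenScore) else score
    n = len(s)
    if n < 3:
        raise ValueError("need >= 3 samples to cluster")
    if not 2 <= k_max <= n:
        raise ValueError("need n >= k_max >= 2")
    sd = s.std(ddof=0)
    x = ((s - s.mean()) / sd if sd > 0 else s * 0.0).to_numpy().reshape(-1, 1)

    wss = []
    for k in range(1, k_max + 1):
        if k == 1:
            wss.append(float(((x - x.mean()) ** 2).sum()))
        else:
            km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(x)
            wss.append(float(km.inertia_))
    if wss[0] <= 1e-12:  # all points identical
        chosen = 1
        assign = pd.Series(1, index=s.index)
        order = list(s.index)
        return chosen, assign, order

    chosen = _elbow_from_wss(wss)

    link = linkage(x, method="complete", metric="euclidean")
    assign = pd.Series(fcluster(link, t=chosen, criterion="maxclust"),
                       index=s.index)
    order = [s.index[i] for i in leaves_list(link)]
    return chosen, assign, order
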