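"""Composite weighted cognitive score from a multi-test battery.

Each test is z-scored over the cohort (error-count tests sign-flipped so
higher always means better), tests are averaged within their cognitive
domain, and the domain scores are averaged into a single global weighted
cognitive performance score per subject. Horn's parallel analysis is
provided to justify the number of latent factors behind the domain
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TestScores", "CompositeScore", "standardize_and_composite",
           "parallel_analysis"]


@dataclass
class TestScores:
    """Subjects x tests battery with domain and direction metadata.

    ``domains`` maps each test column to a cognitive domain name;
    ``directions`` maps each test to +1 (higher is better) or -1
    (error counts: higher is worse).
    """

    scores: pd.DataFrame
    domains: dict[str, str]
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.scores.columns) - set(self.domains)
        if missing:
            raise ValueError(f"tests without a domain assignment: {sorted(missing)}")
        for t in self.scores.columns:
            self.directions.setdefault(t, 1)
            if self.directions[t] not in (-1, 1):
                raise ValueError(f"direction for {t!r} must be +1 or -1")


@dataclass
class CompositeScore:
    """Global weighted cognitive score and its per-domain sub-scores."""

    composite: pd.Series
    domain_scores: pd.DataFrame
    excluded_tests: list[str]


def standardize_and_composite(data: TestScores) -> CompositeScore:
    """Z-score tests, average within domains, average domains.

    Zero-variance tests are excluded with a warning; a domain left empty
    after exclusions is an error. Over the scored cohort the composite has
    mean ~ 0 by construction.
    """
    scores = data.scores
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    z = {}
    excluded = []
    for test in scores.columns:
        col = scores[test].astype(float)
        sd = col.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"test {test!r} has zero variance; excluded")
            excluded.append(test)
            continue
        z[test] = data.directions[test] * (col - col.mean()) / sd
    if not z:
        raise ValueError("all tests excluded (zero variance)")
    zdf = pd.DataFrame(z)

    domain_cols: dict[str, list[str]] = {}
    for test in zdf.columns:
        domain_cols.setdefault(data.domains[test], []).append(test)
    empty = {d for t, d in data.domains.items() if t in excluded} - set(domain_cols)
    if empty:
        raise ValueError(f"domains empty after exclusions: {sorted(empty)}")

    domain_scores = pd.DataFrame(
        {d: zdf[cols].mean(axis=1) for d, cols in domain_cols.items()})
    return CompositeScore(composite=domain_scores.mean(axis=1),
                          domain_scores=domain_scores,
                          excluded_tests=excluded)


def parallel_analysis(scores: pd.DataFrame, n_reps: int = 100,
                      quantile: float = 0.95, seed: int = 0) -> int:
    """Horn's parallel analysis on the test correlation matrix.

    Eigenvalues of the observed correlation matrix are compared, position
    by position, against the ``quantile`` of eigenvalues from ``n_reps``
    same-shape standard-normal datasets. The retained factor count is the
    number of leading observed eigenvalues exceeding their null quantile
    (counting stops at the first failure).
    """
    n, m = scores.shape
    if m < 3:
        raise ValueError("need at least 3 tests")
    if n_reps < 50:
        raise ValueError("n_reps must be >= 50")
    obs = np.linalg.eigvalsh(np.corrcoef(scores.to_numpy(), rowvar=False))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, m))
    for i in range(n_reps):
        sim = rng.standard_normal((n, m))
        null[i] = np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    k = 0
    for o, q in zip(obs, thresh):
        if o > q:
            k += 1
        else:
            break
    return k
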