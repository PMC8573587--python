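"""Seeded generators for synthetic inputs with the statistical structure
the downstream analyses assume.

Four generators are provided:

* negative-binomial microRNA count cohorts with library-size variation,
  a planted multiplicative group effect on a designated signature set and
  linear covariate effects on the log2-mean scale;
* collections of two-group studies with a chosen true standardized mean
  difference and between-study heterogeneity, for meta-analysis work;
* swim trials realizing each named water-maze search strategy through a
  discrete-time kinematic model (constant speed, heading noise);
* multi-test cognitive batteries with a latent-factor structure.

All generators are pure functions of their spec: the same spec and seed
reproduce output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .maze import PoolGeometry, Trajectory

__all__ = [
    "SimCohortSpec",
    "SimMetaSpec",
    "SimTrajectorySpec",
    "MetaStudySamples",
    "simulate_cohort_counts",
    "simulate_meta_studies",
    "simulate_swim_trial",
    "simulate_cognitive_battery",
]


class SimConfigError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class SimCohortSpec:
    """Two-group microRNA count cohort.

    Counts follow a negative binomial with per-sample mean
    ``library_size * feature_proportion``; baseline proportions are
    log-normal. ``log2_effect`` is a planted additive shift on the log2
    scale (i.e. a fold change of ``2**log2_effect``) applied to the
    ``signature_ids`` features in cases. Covariates are (name, effect)
    pairs; covariate values are standard normal per sample and act
    additively on the log2-mean of every feature.
    """

    n_cases: int = 20
    n_controls: int = 20
    n_features: int = 200
    signature_ids: tuple[str, ...] = ("miR-1", "miR-2", "miR-3")
    log2_effect: float = 0.0
    libsize_range: tuple[float, float] = (5e5, 1.5e6)
    dispersion: float = 0.15
    covariates: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise SimConfigError("need >= 2 cases and >= 2 controls")
        if self.dispersion <= 0:
            raise SimConfigError("dispersion must be positive")
        if not (0 < self.libsize_range[0] <= self.libsize_range[1]):
            raise SimConfigError("invalid libsize_range")
        ids = set(self.feature_ids())
        if not set(self.signature_ids) <= ids:
            raise SimConfigError("signature_ids must be a subset of generated feature IDs")

    def feature_ids(self) -> list[str]:
        return [f"miR-{i + 1}" for i in range(self.n_features)]


def simulate_cohort_counts(spec: SimCohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a (features x samples) count matrix and its sample metadata.

    Returns ``(counts, meta)``: integer counts indexed by feature ID, and
    per-sample metadata with ``group`` (case/control), one column per
    covariate and a latent ``phenotype`` column (standard-normal score
    shifted down by the eigen-level group effect direction, handy as a
    correlate in tests).
    """
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_ids()
    n = spec.n_cases + spec.n_controls
    samples = [f"S{i + 1}" for i in range(n)]
    group = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)

    # log-normal baseline composition
    props = rng.lognormal(mean=0.0, sigma=1.5, size=spec.n_features)
    props /= props.sum()
    libsize = rng.uniform(*spec.libsize_range, size=n)

    log2_mu = (np.log2(props)[:, None] + np.log2(libsize)[None, :])
    sig_mask = np.isin(features, spec.signature_ids)
    log2_mu[np.ix_(sig_mask, group == "case")] += spec.log2_effect

    meta = pd.DataFrame({"sample_id": samples, "group": group}).set_index("sample_id")
    cov_targets: dict[str, list[str]] = {}
    for name, beta in spec.covariates:
        vals = rng.standard_normal(n)
        meta[name] = vals
        # a covariate hitting every feature equally is indistinguishable
        # from library size; affect a random half of the features instead
        mask = rng.random(spec.n_features) < 0.5
        cov_targets[name] = [f for f, m in zip(features, mask) if m]
        log2_mu[mask] += beta * vals[None, :]

    mu = np.exp2(log2_mu)
    size = 1.0 / spec.dispersion  # NB: var = mu + dispersion * mu^2
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    meta["phenotype"] = rng.standard_normal(n) - 0.5 * np.sign(spec.log2_effect) * (
        group == "case")
    meta.attrs["seed"] = spec.seed
    meta.attrs["covariate_targets"] = cov_targets
    return pd.DataFrame(counts, index=features, columns=samples), meta


@dataclass(frozen=True)
class SimMetaSpec:
    """A collection of two-group studies for meta-analysis.

    Each study draws a true effect ``theta_i ~ Normal(true_smd, tau^2)``
    and then unit-variance normal observations whose group means differ by
    ``theta_i`` (so the effect is in SD units).
    """

    k_studies: int = 15
    true_smd: float = 1.0
    tau: float = 0.2
    group_sizes: tuple[tuple[int, int], ...] = tuple((30, 30) for _ in range(15))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies != len(self.group_sizes):
            raise SimConfigError("k_studies must equal len(group_sizes)")
        if self.tau < 0:
            raise SimConfigError("tau must be non-negative")
        if any(n1 < 2 or n2 < 2 for n1, n2 in self.group_sizes):
            raise SimConfigError("all group sizes must be >= 2")


@dataclass(frozen=True)
class MetaStudySamples:
    """Raw observations of one simulated two-group study."""

    label: str
    group1: np.ndarray
    group2: np.ndarray


def simulate_meta_studies(spec: SimMetaSpec) -> list[MetaStudySamples]:
    rng = np.random.default_rng(spec.seed)
    out = []
    for i, (n1, n2) in enumerate(spec.group_sizes):
        theta = rng.normal(spec.true_smd, spec.tau)
        g1 = rng.standard_normal(n1) + theta
        g2 = rng.standard_normal(n2)
        out.append(MetaStudySamples(label=f"study-{i + 1}", group1=g1, group2=g2))
    return out


@dataclass(frozen=True)
class SimTrajectorySpec:
    """One simulated swim trial of a named search strategy.

    The swim is integrated at ``sampling_hz`` with constant speed and
    strategy-specific heading dynamics; isotropic Gaussian positional
    noise of ``noise_sd`` cm emulates tracker jitter. The trial ends at
    platform contact or after ``max_duration`` seconds.
    """

    strategy: str = "direct"
    pool_radius: float = 60.0
    platform_center: tuple[float, float] = (21.2, 21.2)
    platform_halfwidth: float = 5.5
    sampling_hz: float = 10.0
    speed: float = 18.0
    noise_sd: float = 0.5
    max_duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {"direct", "corrected", "short_chaining", "long_chaining",
                 "circling", "random"}
        if self.strategy not in valid:
            raise SimConfigError(f"unknown strategy {self.strategy!r}")
        if self.sampling_hz <= 0 or self.max_duration <= 0:
            raise SimConfigError("sampling_hz and max_duration must be positive")
        # geometry validity delegated to PoolGeometry
        self.geometry()

    def geometry(self) -> PoolGeometry:
        return PoolGeometry(center=(0.0, 0.0), radius=self.pool_radius,
                            platform_center=self.platform_center,
                            platform_halfwidth=self.platform_halfwidth)


def _wall_clamp(pos: np.ndarray, radius: float) -> np.ndarray:
    r = math.hypot(*pos)
    if r > radius:
        pos = pos * (radius / r)
    return pos


def simulate_swim_trial(spec: SimTrajectorySpec) -> Trajectory:
    """Generate one trial realizing ``spec.strategy``.

    direct          near-straight swim from the start to the platform
    corrected       one deliberate heading correction midway
    short_chaining  annular sweep at the platform's radial distance,
                    terminating at platform contact within a fraction of
                    a lap
    long_chaining   persistent annular sweep slightly off the platform
                    radius, lasting essentially the whole trial
    circling        perimeter-hugging sweep
    random          unbiased correlated random walk
    """
    rng = np.random.default_rng(spec.seed)
    geo = spec.geometry()
    r = spec.pool_radius
    dt = 1.0 / spec.sampling_hz
    n_max = int(spec.max_duration * spec.sampling_hz)
    plat = np.asarray(spec.platform_center, dtype=float)
    plat_angle = math.atan2(plat[1], plat[0])
    d_plat = float(np.hypot(*plat))

    start_r = 0.93 * r
    if spec.strategy in ("short_chaining",):
        # enter the annulus a long arc before the platform: the sweep,
        # not the approach, dominates the path
        arc = rng.uniform(1.4 * math.pi, 1.9 * math.pi)
        sweep_dir = rng.choice([-1.0, 1.0])
        start_angle = plat_angle - sweep_dir * arc
    else:
        start_angle = plat_angle + math.pi + rng.uniform(-1.0, 1.0)
    pos = start_r * np.array([math.cos(start_angle), math.sin(start_angle)])

    xs, ys = [pos[0]], [pos[1]]
    heading = math.atan2(plat[1] - pos[1], plat[0] - pos[0])
    corrected_done = False
    if spec.strategy == "corrected":
        heading += rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.2)
    if spec.strategy == "random":
        heading = rng.uniform(-math.pi, math.pi)
    sweep_dir = rng.choice([-1.0, 1.0]) if spec.strategy != "short_chaining" else sweep_dir

    # annulus radii: short chaining sits on the platform ring, long chaining
    # and circling deliberately avoid platform contact
    ring = {"short_chaining": d_plat,
            "long_chaining": min(d_plat + spec.platform_halfwidth + 6.0, 0.85 * r),
            "circling": 0.95 * r}.get(spec.strategy)

    heading_noise = {"direct": 0.06, "corrected": 0.06, "random": 0.5}.get(
        spec.strategy, 0.05)
    if spec.noise_sd == 0:  # noiseless spec: fully deterministic kinematics
        heading_noise = 0.0

    for step in range(n_max):
        if spec.strategy in ("direct", "corrected"):
            target = math.atan2(plat[1] - pos[1], plat[0] - pos[0])
            if spec.strategy == "corrected" and not corrected_done:
                travelled = spec.speed * step * dt
                if travelled < 0.45 * (start_r + d_plat):
                    target = heading  # keep the initial (wrong) heading
                else:
                    corrected_done = True
            heading = target + rng.normal(0.0, heading_noise)
        elif spec.strategy == "random":
            heading += rng.normal(0.0, heading_noise)
        else:  # annular sweeps: advance tangentially, steer onto the ring
            cur_r = math.hypot(*pos)
            cur_a = math.atan2(pos[1], pos[0])
            tangent = cur_a + sweep_dir * math.pi / 2
            # positive correction rotates the heading toward the pool
            # center when outside the ring, outward when inside
            correction = float(np.clip((cur_r - ring) * 0.15, -1.2, 1.2))
            heading = tangent + sweep_dir * correction
            heading += rng.normal(0.0, heading_noise)

        pos = pos + spec.speed * dt * np.array([math.cos(heading), math.sin(heading)])
        if spec.strategy == "random" and math.hypot(*pos) > 0.95 * r:
            # reflect back toward the interior
            heading = math.atan2(-pos[1], -pos[0]) + rng.normal(0.0, 0.3)
        pos = _wall_clamp(pos, 0.97 * r)
        xs.append(pos[0])
        ys.append(pos[1])
        reaches_platform = spec.strategy in ("direct", "corrected",
                                             "short_chaining", "random")
        if reaches_platform and geo.in_platform(pos[0], pos[1]):
            break

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if spec.noise_sd > 0:
        xs = xs + rng.normal(0.0, spec.noise_sd, size=xs.size)
        ys = ys + rng.normal(0.0, spec.noise_sd, size=ys.size)
        rad = np.hypot(xs, ys)
        over = rad > r
        if over.any():  # clamp jittered points back onto the pool
            scale = np.where(over, r / rad, 1.0)
            xs, ys = xs * scale, ys * scale
    t = np.arange(xs.size) * dt
    return Trajectory(trial_id=f"{spec.strategy}-{spec.seed}",
                      t=t, x=xs, y=ys, geometry=geo)


def simulate_cognitive_battery(n_subjects: int,
                               loadings: np.ndarray,
                               noise_sd: float = 1.0,
                               seed: int = 0) -> pd.DataFrame:
    """Latent-factor test battery: scores = factors @ loadings.T + noise.

    ``loadings`` is a (tests x factors) matrix; latent factors are
    independent standard normals per subject. Returns a subjects x tests
    DataFrame (``subject_id`` index, ``test_1..test_m`` columns).
    """
    if n_subjects < 3:
        raise SimConfigError("need >= 3 subjects")
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if not np.all(np.isfinite(loadings)):
        raise SimConfigError("loadings must be finite")
    rng = np.random.default_rng(seed)
    n_tests, n_factors = loadings.shape
    factors = rng.standard_normal((n_subjects, n_factors))
    scores = factors @ loadings.T + rng.normal(0.0, noise_sd,
                                               size=(n_subjects, n_tests))
    return pd.DataFrame(scores,
                        index=[f"subj_{i + 1}" for i in range(n_subjects)],
                        columns=[f"test_{j + 1}" for j in range(n_tests)])
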