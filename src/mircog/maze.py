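"""Morris water-maze trajectory analysis.

Implements the modified MUST-C pipeline: 17 scalar descriptors of a single
swim trial, rule-based classification of the search strategy used, the
per-day weighted cognitive score built from strategy frequencies, and
50x50 occupancy-density maps.

A trial is a time-ordered sequence of planar positions recorded by a
tracker, together with the pool geometry (circular pool, square escape
platform submerged in one quadrant). Strategies that require an intact
spatial map of the platform location ("direct", "corrected", "short
chaining") carry positive scores (10, 9.5, 9); spatially unspecific
strategies ("long chaining", "circling", "random") score 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

__all__ = [
    "PoolGeometry",
    "Trajectory",
    "TrialFeatures",
    "StrategyRuleset",
    "DensityMap",
    "STRATEGY_SCORES",
    "STRATEGY_LABELS",
    "FEATURE_NAMES",
    "extract_trial_features",
    "classify_strategy",
    "default_ruleset",
    "daily_cognitive_score",
    "occupancy_density",
    "read_trajectories_csv",
]

#: Strategy score assignments: hippocampus-dependent strategies score
#: 10 / 9.5 / 9; spatially unspecific strategies score 0.
STRATEGY_SCORES: dict[str, float] = {
    "direct": 10.0,
    "corrected": 9.5,
    "short_chaining": 9.0,
    "long_chaining": 0.0,
    "circling": 0.0,
    "random": 0.0,
}

STRATEGY_LABELS = tuple(STRATEGY_SCORES)

FEATURE_NAMES = (
    "avg_proximity_to_platform",
    "dist_centroid_to_platform",
    "sum_absolute_angles",
    "mean_dist_from_perimeter",
    "total_duration",
    "n_quadrant_changes",
    "max_time_one_quadrant",
    "sum_relative_angles_x",
    "cumulative_angle_y",
    "platform_crossings",
    "var_dist_from_perimeter",
    "mean_velocity",
    "distance_traveled",
    "total_coverage",
    "local_density",
    "var_dist_to_platform",
    "path_efficiency",
)


class MazeConfigError(ValueError):
    """Invalid geometry or ruleset configuration."""


@dataclass(frozen=True)
class PoolGeometry:
    """Circular pool with a square escape platform.

    Parameters
    ----------
    center : (x, y) pool center in cm.
    radius : pool radius in cm (default 60, i.e. the 1.2 m pool).
    platform_center : (x, y) center of the platform square.
    platform_halfwidth : half the platform side in cm (default 5.5 for an
        11 x 11 cm platform).
    quadrant_angle : orientation (radians) of the first quadrant axis;
        quadrants are the four 90-degree sectors around ``center``.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 60.0
    platform_center: tuple[float, float] = (21.2, 21.2)
    platform_halfwidth: float = 5.5
    quadrant_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise MazeConfigError("pool radius must be positive")
        cx, cy = self.center
        px, py = self.platform_center
        # farthest platform corner must stay inside the pool circle
        corner = math.hypot(abs(px - cx) + self.platform_halfwidth,
                            abs(py - cy) + self.platform_halfwidth)
        if corner > self.radius:
            raise MazeConfigError(
                "platform square extends outside the pool circle")

    def in_platform(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        px, py = self.platform_center
        h = self.platform_halfwidth
        return (np.abs(np.asarray(x) - px) <= h) & (np.abs(np.asarray(y) - py) <= h)

    def quadrant(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        ang = np.arctan2(np.asarray(y) - cy, np.asarray(x) - cx) - self.quadrant_angle
        return (np.floor(ang / (np.pi / 2)) % 4).astype(int)


@dataclass
class Trajectory:
    """One swim trial: strictly increasing times and planar positions (cm)."""

    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: PoolGeometry

    #: fractional tolerance on the pool radius for point containment
    radius_tol: float = 0.05

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError(f"trial {self.trial_id}: t/x/y length mismatch")
        if len(self.t) < 2:
            raise ValueError(f"trial {self.trial_id}: need >= 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"trial {self.trial_id}: t must be strictly increasing")
        cx, cy = self.geometry.center
        r = np.hypot(self.x - cx, self.y - cy)
        if np.any(r > self.geometry.radius * (1 + self.radius_tol)):
            raise ValueError(
                f"trial {self.trial_id}: positions outside pool radius")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class TrialFeatures:
    """The 17 scalar descriptors of one swim trial (distances in cm)."""

    avg_proximity_to_platform: float
    dist_centroid_to_platform: float
    sum_absolute_angles: float
    mean_dist_from_perimeter: float
    total_duration: float
    n_quadrant_changes: int
    max_time_one_quadrant: float
    sum_relative_angles_x: float
    cumulative_angle_y: float
    platform_crossings: int
    var_dist_from_perimeter: float
    mean_velocity: float
    distance_traveled: float
    total_coverage: float
    local_density: float
    var_dist_to_platform: float
    path_efficiency: float
    degenerate_path: bool = field(default=False, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_trial_features(trajectory: Trajectory,
                           angle_eps: float = 0.1) -> TrialFeatures:
    """Compute all 17 trial descriptors.

    Angle features are computed from successive displacement vectors;
    steps shorter than ``angle_eps`` cm are skipped so that tracker jitter
    around a resting animal does not dominate the heading sequence.

    A zero-length path (animal never moves) is degenerate: velocity is
    reported as 0, path efficiency as 1, and the result is flagged via
    ``degenerate_path``.
    """
    geo = trajectory.geometry
    t, x, y = trajectory.t, trajectory.x, trajectory.y
    if len(t) < 3:
        raise ValueError(
            f"trial {trajectory.trial_id}: angle features need >= 3 samples")
    cx, cy = geo.center
    px, py = geo.platform_center

    d_platform = np.hypot(x - px, y - py)
    d_center = np.hypot(x - cx, y - cy)
    d_perimeter = geo.radius - d_center

    dx, dy = np.diff(x), np.diff(y)
    step_len = np.hypot(dx, dy)
    path_len = float(step_len.sum())
    straight = float(math.hypot(x[-1] - x[0], y[-1] - y[0]))
    degenerate = path_len <= 0
    if degenerate:
        path_eff = 1.0
    else:
        path_eff = min(straight / path_len, 1.0)

    duration = float(t[-1] - t[0])
    velocity = 0.0 if degenerate else path_len / duration

    # headings over non-trivial steps only
    keep = step_len >= angle_eps
    if keep.sum() >= 2:
        headings = np.arctan2(dy[keep], dx[keep])
        turns = np.diff(headings)
        turns = (turns + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
        sum_abs_angles = float(np.abs(turns).sum())
        # relative angles: signed heading of each step against the x axis,
        # and against the y axis (the paper defines both axis variants)
        rel_x = np.arctan2(dy[keep], dx[keep])
        rel_y = np.arctan2(dx[keep], dy[keep])
        sum_rel_x = float(rel_x.sum())
        cum_y = float(rel_y.sum())
    else:
        sum_abs_angles = sum_rel_x = cum_y = 0.0

    quad = geo.quadrant(x, y)
    quad_changes = int(np.count_nonzero(np.diff(quad) != 0))
    frac = np.bincount(quad, minlength=4) / len(quad)
    max_time_quadrant = float(frac.max())

    inside = geo.in_platform(x, y)
    crossings = int(np.count_nonzero(inside[1:] & ~inside[:-1]))
    if inside[0]:
        crossings += 1

    pts = np.column_stack([x, y])
    try:
        hull_area = float(ConvexHull(pts).volume)  # 2-D "volume" is area
    except QhullError:  # collinear / coincident points
        hull_area = 0.0
    coverage = hull_area / (math.pi * geo.radius**2)

    local_density = float(pdist(pts).mean()) if len(pts) > 1 else 0.0

    return TrialFeatures(
        avg_proximity_to_platform=float(d_platform.mean()),
        dist_centroid_to_platform=float(
            math.hypot(x.mean() - px, y.mean() - py)),
        sum_absolute_angles=sum_abs_angles,
        mean_dist_from_perimeter=float(d_perimeter.mean()),
        total_duration=duration,
        n_quadrant_changes=quad_changes,
        max_time_one_quadrant=max_time_quadrant,
        sum_relative_angles_x=sum_rel_x,
        cumulative_angle_y=cum_y,
        platform_crossings=crossings,
        var_dist_from_perimeter=float(d_perimeter.var()),
        mean_velocity=velocity,
        distance_traveled=path_len,
        total_coverage=coverage,
        local_density=local_density,
        var_dist_to_platform=float(d_platform.var()),
        path_efficiency=path_eff,
        degenerate_path=degenerate,
    )


# ---------------------------------------------------------------------------
# strategy classification
# ---------------------------------------------------------------------------

@dataclass
class StrategyRuleset:
    """Ordered decision list over trial features.

    Each rule is ``(label, {feature: (lo, hi)})``: the rule fires when every
    referenced feature lies in its closed interval (``None`` = unbounded).
    Rules are evaluated in order; the first match wins, with a fixed
    fallback label (default ``"random"``).
    """

    rules: list[tuple[str, dict[str, tuple[float | None, float | None]]]]
    fallback: str = "random"

    def __post_init__(self) -> None:
        for label, preds in self.rules:
            if label not in STRATEGY_SCORES:
                raise MazeConfigError(f"unknown strategy label {label!r}")
            for name in preds:
                if name not in FEATURE_NAMES:
                    raise MazeConfigError(f"rule references unknown feature {name!r}")
        if self.fallback not in STRATEGY_SCORES:
            raise MazeConfigError(f"unknown fallback label {self.fallback!r}")


def default_ruleset(geometry: PoolGeometry,
                    max_duration: float = 60.0) -> StrategyRuleset:
    """Build the default classification rules for a given pool geometry.

    Thresholds are expressed relative to the pool radius and the radial
    distance of the platform from the pool center, so the same relative
    rules transfer across arena sizes. The original MUST-C thresholds are
    not published; these defaults are calibrated against the kinematic
    trial simulator and are fully editable configuration.
    """
    r = geometry.radius
    d_plat = math.hypot(geometry.platform_center[0] - geometry.center[0],
                        geometry.platform_center[1] - geometry.center[1])
    band = geometry.platform_halfwidth + 0.15 * r
    ann_lo = max(r - d_plat - band, 0.0)  # chaining annulus, as perimeter dist
    ann_hi = r - d_plat + band
    ring_var = (0.15 * r) ** 2
    rules = [
        ("direct", {"path_efficiency": (0.80, None)}),
        ("corrected", {"path_efficiency": (0.50, None)}),
        ("circling", {"mean_dist_from_perimeter": (None, 0.12 * r),
                      "sum_absolute_angles": (1.5 * math.pi, None)}),
        ("short_chaining", {"mean_dist_from_perimeter": (ann_lo, ann_hi),
                            "var_dist_from_perimeter": (None, ring_var),
                            "total_duration": (None, 0.7 * max_duration)}),
        ("long_chaining", {"mean_dist_from_perimeter": (ann_lo, ann_hi),
                           "var_dist_from_perimeter": (None, ring_var)}),
    ]
    return StrategyRuleset(rules=rules)


def classify_strategy(features: TrialFeatures,
                      ruleset: StrategyRuleset) -> str:
    """Assign a search-strategy label: first matching rule, else fallback."""
    feats = features.as_dict()
    for value in feats.values():
        if not np.isfinite(value):
            raise ValueError("features must be finite for classification")
    for label, preds in ruleset.rules:
        ok = True
        for name, (lo, hi) in preds.items():
            v = feats[name]
            if lo is not None and v < lo:
                ok = False
                break
            if hi is not None and v > hi:
                ok = False
                break
        if ok:
            return label
    return ruleset.fallback


# ---------------------------------------------------------------------------
# daily cognitive score
# ---------------------------------------------------------------------------

def daily_cognitive_score(labels: pd.DataFrame) -> float:
    """Weighted cognitive score for one training day.

    ``labels`` is a mice x trials table of strategy labels. With n trials
    and mc mice, the score is

        (1/n) * sum_i (Sdf_i*10 + Sscf_i*9.5 + Slcf_i*9) / mc

    where Sdf_i, Sscf_i, Slcf_i count the mice using the direct, corrected
    and short-chaining strategy in trial i. The score lives in [0, 10];
    10 means every mouse swam directly to the platform in every trial.
    """
    if labels.isna().any().any():
        missing = [(m, tr) for m in labels.index for tr in labels.columns
                   if pd.isna(labels.loc[m, tr])]
        raise ValueError(f"missing strategy labels for (mouse, trial): {missing}")
    bad = set(np.unique(labels.to_numpy())) - set(STRATEGY_SCORES)
    if bad:
        raise ValueError(f"unknown strategy labels: {sorted(bad)}")
    n_trials = labels.shape[1]
    n_mice = labels.shape[0]
    if n_trials == 0 or n_mice == 0:
        raise ValueError("labels table must be non-empty")
    total = 0.0
    for col in labels.columns:
        counts = labels[col].value_counts()
        total += (counts.get("direct", 0) * 10.0
                  + counts.get("corrected", 0) * 9.5
                  + counts.get("short_chaining", 0) * 9.0) / n_mice
    return total / n_trials


# ---------------------------------------------------------------------------
# occupancy density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Smoothed, globally min-max normalized 50x50 occupancy grid."""

    grid: np.ndarray
    raw: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    norm_bounds: tuple[float, float]


def occupancy_density(trajectories: Sequence[Trajectory],
                      groups: Sequence[str],
                      n_bins: int = 50,
                      smooth_sigma: float = 1.0) -> dict[str, DensityMap]:
    """Per-group occupancy density on an ``n_bins`` x ``n_bins`` grid.

    Position samples are binned over the pool's bounding square, converted
    to densities (cell count / total count per group), Gaussian-smoothed
    (``smooth_sigma`` in cells), and min-max normalized using the global
    minimum and maximum over *all* groups so maps are directly comparable.
    """
    if len(trajectories) != len(groups):
        raise ValueError("one group label per trajectory required")
    if not trajectories:
        raise ValueError("no trajectories given")
    geo = trajectories[0].geometry
    for traj in trajectories:
        if traj.geometry != geo:
            raise ValueError("all trajectories must share one geometry")
    cx, cy = geo.center
    r = geo.radius
    x_edges = np.linspace(cx - r, cx + r, n_bins + 1)
    y_edges = np.linspace(cy - r, cy + r, n_bins + 1)

    raw: dict[str, np.ndarray] = {}
    smoothed: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(groups):
        xs = np.concatenate([tr.x for tr, gg in zip(trajectories, groups) if gg == g])
        ys = np.concatenate([tr.y for tr, gg in zip(trajectories, groups) if gg == g])
        if xs.size == 0:
            raise ValueError(f"group {g!r} has no position samples")
        counts, _, _ = np.histogram2d(xs, ys, bins=[x_edges, y_edges])
        dens = counts / counts.sum()
        raw[g] = dens
        smoothed[g] = gaussian_filter(dens, sigma=smooth_sigma)

    lo = min(m.min() for m in smoothed.values())
    hi = max(m.max() for m in smoothed.values())
    span = hi - lo
    if span <= 0:
        warnings.warn("all density cells identical; normalization degenerate")
        span = 1.0
    return {
        g: DensityMap(grid=(m - lo) / span, raw=raw[g],
                      x_edges=x_edges, y_edges=y_edges, norm_bounds=(lo, hi))
        for g, m in smoothed.items()
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trajectories_csv(path, geometry: PoolGeometry) -> pd.DataFrame:
    """Read a trajectory table (trial_id, mouse_id, day, t_sec, x_cm, y_cm).

    Returns the table with one :class:`Trajectory` built per trial_id,
    stored in a ``trajectory`` column of a per-trial frame (trial_id,
    mouse_id, day, trajectory). Malformed rows abort with line numbers.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "mouse_id", "day", "t_sec", "x_cm", "y_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    bad = df[["t_sec", "x_cm", "y_cm"]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"malformed trajectory rows at lines {lines}")
    records = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        sub = sub.sort_values("t_sec")
        traj = Trajectory(trial_id=str(trial_id), t=sub["t_sec"].to_numpy(),
                          x=sub["x_cm"].to_numpy(), y=sub["y_cm"].to_numpy(),
                          geometry=geometry)
        rec = {"trial_id": str(trial_id),
               "mouse_id": sub["mouse_id"].iloc[0],
               "day": sub["day"].iloc[0],
               "trajectory": traj}
        if "group" in sub.columns:
            rec["group"] = sub["group"].iloc[0]
        records.append(rec)
    return pd.DataFrame(records)
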