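"""Spatial model: volunteer placement and distance-dependent travel times.

Volunteers are placed uniformly at random in a circular dispatch region
centred on the patient.  Only the straight-line distance to the patient
matters for the simulation, so locations are sampled radially: if ``U`` is
uniform on [0, 1], then ``r = R * sqrt(U)`` has the area-uniform law
``P(D <= d) = (d / R)**2``.

Travel time follows a distance-dependent speed model: walking/running speed
in km/h grows linearly with distance (volunteers far away tend to use faster
modes), ``y(x) = intercept + slope * x`` for distance ``x`` in metres.  The
induced travel time in minutes is ``60 x / (1000 * y(x))``; with the default
coefficients this is ``60 x / (1830 + 10.8 x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiskConfig",
    "SpeedModel",
    "SpeedFit",
    "DEFAULT_SPEED_MODEL",
    "sample_distances",
    "travel_time_min",
    "fit_speed_model",
    "load_speed_pairs",
]


@dataclass(frozen=True)
class DiskConfig:
    """Dispatch disk: ``n_volunteers`` placed uniformly within ``radius_m``."""

    n_volunteers: int
    radius_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_volunteers < 0:
            raise ValueError(f"n_volunteers must be >= 0, got {self.n_volunteers}")
        if not self.radius_m > 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")


@dataclass(frozen=True)
class SpeedModel:
    """Linear distance->speed law ``speed_kmh = intercept + slope * distance_m``."""

    intercept_kmh: float = 1.83
    slope_kmh_per_m: float = 0.0108

    def __post_init__(self) -> None:
        if not self.intercept_kmh > 0:
            raise ValueError("intercept_kmh must be > 0")

    def speed_kmh(self, distance_m):
        """Predicted speed in km/h at the given distance(s) in metres."""
        return self.intercept_kmh + self.slope_kmh_per_m * np.asarray(distance_m, dtype=float)

    def validate_for_radius(self, radius_m: float) -> None:
        """Reject a model whose predicted speed is non-positive anywhere in [0, R]."""
        # speed is linear in distance, so it suffices to check the endpoints
        if min(self.speed_kmh(0.0), self.speed_kmh(radius_m)) <= 0:
            raise ValueError(
                f"speed model predicts non-positive speed within [0, {radius_m}] m"
            )


DEFAULT_SPEED_MODEL = SpeedModel()


def sample_distances(cfg: DiskConfig, rng) -> np.ndarray:
    """Sample volunteer distances (metres), sorted ascending.

    Sorting establishes the distance order used by every alerting policy:
    a more distant volunteer is only alerted once all closer ones are.

    Parameters
    ----------
    cfg : DiskConfig
    rng : int seed or :class:`numpy.random.Generator`
    """
    rng = np.random.default_rng(rng)
    if cfg.n_volunteers == 0:
        return np.empty(0, dtype=float)
    r = cfg.radius_m * np.sqrt(rng.random(cfg.n_volunteers))
    r.sort()
    return r


def travel_time_min(distance_m, model: SpeedModel = DEFAULT_SPEED_MODEL):
    """Travel time in minutes for straight-line distance(s) in metres.

    ``time = 60 x / (1000 * (intercept + slope * x))``; with the default
    model this is ``60 x / (1830 + 10.8 x)`` (4.75 min at 1 km).
    """
    x = np.asarray(distance_m, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance_m must be >= 0")
    t = 60.0 * x / (1000.0 * model.speed_kmh(x))
    return float(t) if np.isscalar(distance_m) else t


@dataclass(frozen=True)
class SpeedFit:
    """Result of fitting a :class:`SpeedModel` to observed travel data."""

    model: SpeedModel
    r_squared: float
    block_midpoint_m: np.ndarray
    block_median_speed_kmh: np.ndarray


def fit_speed_model(
    distance_m,
    travel_time_s,
    block_width_m: float = 100.0,
) -> SpeedFit:
    """Fit the linear distance->speed law from (distance, travel time) pairs.

    Procedure: observations with zero travel time are excluded; distances are
    binned into ``block_width_m`` blocks; the first block (0-100 m with the
    default width) is excluded as unreliable; the median speed (km/h) of each
    remaining block is regressed by ordinary least squares on the block
    midpoint distance.

    Raises
    ------
    ValueError
        If fewer than 2 usable blocks remain after the exclusions.
    """
    d = np.asarray(distance_m, dtype=float)
    t = np.asarray(travel_time_s, dtype=float)
    if d.shape != t.shape:
        raise ValueError("distance_m and travel_time_s must have the same length")
    if np.any(t < 0) or np.any(d < 0):
        raise ValueError("distances and travel times must be non-negative")

    keep = t > 0
    d, t = d[keep], t[keep]
    block = np.floor(d / block_width_m).astype(int)
    keep = block >= 1  # drop the 0..block_width block
    d, t, block = d[keep], t[keep], block[keep]

    speed_kmh = 3.6 * d / t  # m/s -> km/h
    blocks = np.unique(block)
    if blocks.size < 2:
        raise ValueError("need at least 2 usable distance blocks to fit a speed model")
    medians = np.array([np.median(speed_kmh[block == b]) for b in blocks])
    midpoints = (blocks + 0.5) * block_width_m

    res = stats.linregress(midpoints, medians)
    model = SpeedModel(intercept_kmh=float(res.intercept), slope_kmh_per_m=float(res.slope))
    return SpeedFit(
        model=model,
        r_squared=float(res.rvalue**2),
        block_midpoint_m=midpoints,
        block_median_speed_kmh=medians,
    )


def load_speed_pairs(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``distance_m,travel_time_s`` CSV (header required, UTF-8)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"distance_m", "travel_time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"speed-fit CSV missing columns: {sorted(missing)}")
    return df["distance_m"].to_numpy(float), df["travel_time_s"].to_numpy(float)
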