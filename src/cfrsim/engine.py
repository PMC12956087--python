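"""Nested Monte Carlo engine.

Two sources of uncertainty are simulated: the distances between volunteers
and the patient (outer replications — one set of uniformly placed volunteers
per simulated arrest) and the volunteers' view delays and replies (inner
replications — jointly resampled responses for the same locations).  Each
inner replication is one simulated incident; the engine resolves the alert
schedule against the pre-drawn responses, computes each accepter's arrival
time (alert + view delay + travel), and converts the first arrival into a
survival probability.

Timeline per incident (all seconds since collapse unless noted): a 60 s
witness delay and a 124 s triage delay precede system activation at "time
0"; alert times, view delays and travel all accrue after activation; the
ambulance arrives at T_EMS = 13 min after collapse regardless.  Time to CPR
is ``min(witness + triage + first volunteer arrival, T_EMS)``.

Reproducibility: every random stream is derived from ``SimConfig.master_seed``
via ``numpy.random.SeedSequence`` with a counter-based spawn key per
(policy-stream, outer replication), so runs are deterministic and adding
policies does not perturb existing streams.  Passing the same ``stream_key``
to several :func:`run_policy` calls couples them (common random numbers:
identical distance sets and per-rank response tables), which sharpens policy
comparisons; the default is an independent stream per (policy, density).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .behavior import BehaviorModel, Reply
from .geometry import DiskConfig, SpeedModel, DEFAULT_SPEED_MODEL, sample_distances, travel_time_min
from .outcomes import SurvivalModel, DEFAULT_SURVIVAL_MODEL, aggregate, survival_prob
from .policy import PolicySpec, schedule_alerts

__all__ = [
    "SimConfig",
    "IncidentResult",
    "OuterSummary",
    "simulate_incident",
    "run_policy",
    "evaluate_policy",
    "policy_stream_key",
]


@dataclass(frozen=True)
class SimConfig:
    """Replication counts, timing constants and the master seed.

    Defaults are the full experimental design (1,000 location sets x 10,000
    response draws); pass smaller counts for desk-scale runs.
    """

    n_outer: int = 1000
    n_inner: int = 10000
    t_ems_min: float = 13.0
    witness_delay_s: float = 60.0
    triage_delay_s: float = 124.0
    coverage_threshold_s: float = 300.0
    annual_ohcas: int = 5141
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("replication counts must be >= 1")
        for name in ("t_ems_min", "witness_delay_s", "triage_delay_s", "coverage_threshold_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.annual_ohcas < 1:
            raise ValueError("annual_ohcas must be >= 1")

    def desk_scale(self, n_outer: int = 50, n_inner: int = 200) -> "SimConfig":
        """A reduced-replication copy for quick exploration."""
        return replace(self, n_outer=n_outer, n_inner=n_inner)


@dataclass(frozen=True)
class IncidentResult:
    """Raw outcome of one simulated incident."""

    first_arrival_s: float  # seconds since activation; inf if nobody arrives
    n_alerts: int
    n_arrivals: int
    covered: bool
    survival_prob: float


@dataclass(frozen=True)
class OuterSummary:
    """Inner-replication means for one volunteer-location set."""

    coverage: float
    mean_survival: float
    mean_alerts: float
    mean_redundant: float
    frac_two_plus: float
    n_inner: int


def policy_stream_key(spec: PolicySpec, disk: DiskConfig) -> int:
    """Stable 31-bit stream identifier for a (policy, density) pair."""
    tag = f"{spec.as_string()}|n={disk.n_volunteers}|r={disk.radius_m:g}"
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def _outer_rng(cfg: SimConfig, stream_key: int, outer_rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(cfg.master_seed, spawn_key=(stream_key, outer_rep))
    return np.random.default_rng(ss)


def _t_cpr_min(first_arrival_s, cfg: SimConfig):
    """Minutes from collapse to first CPR, truncated at ambulance arrival."""
    raw = (cfg.witness_delay_s + cfg.triage_delay_s + np.asarray(first_arrival_s)) / 60.0
    return np.minimum(raw, cfg.t_ems_min)


def _incident_from_row(
    spec: PolicySpec,
    view_delays: np.ndarray,
    replies: np.ndarray,
    travel_s: np.ndarray,
    cfg: SimConfig,
    survival_model: SurvivalModel,
) -> IncidentResult:
    """Resolve one incident from a pre-drawn per-rank response row."""
    n = travel_s.size
    events = schedule_alerts(spec, n, view_delays, replies)
    first = math.inf
    n_arrivals = 0
    for ev in events:
        r = ev.volunteer_rank
        if replies[r] == Reply.ACCEPT:
            n_arrivals += 1
            arrival = ev.alert_time_s + view_delays[r] + travel_s[r]
            if arrival < first:
                first = arrival
    sp = float(survival_prob(float(_t_cpr_min(first, cfg)), cfg.t_ems_min, survival_model))
    return IncidentResult(
        first_arrival_s=first,
        n_alerts=len(events),
        n_arrivals=n_arrivals,
        covered=first <= cfg.coverage_threshold_s,
        survival_prob=sp,
    )


def simulate_incident(
    spec: PolicySpec,
    distances: np.ndarray,
    behavior: BehaviorModel,
    cfg: SimConfig,
    rng,
    speed_model: SpeedModel = DEFAULT_SPEED_MODEL,
    survival_model: SurvivalModel = DEFAULT_SURVIVAL_MODEL,
) -> IncidentResult:
    """Simulate a single incident for one sorted distance set.

    Draws one joint (view delay, reply) per volunteer, resolves the alert
    schedule, and scores the incident.
    """
    distances = np.asarray(distances, dtype=float)
    if np.any(np.diff(distances) < 0):
        raise ValueError("distances must be sorted ascending (distance rank order)")
    n = distances.size
    delays, replies = behavior.draw(rng, n)
    travel_s = 60.0 * travel_time_min(distances, speed_model) if n else np.empty(0)
    return _incident_from_row(spec, delays, replies, travel_s, cfg, survival_model)


def _summarize_send(
    k: int,
    delays: np.ndarray,
    replies: np.ndarray,
    travel_s: np.ndarray,
    cfg: SimConfig,
    survival_model: SurvivalModel,
) -> OuterSummary:
    """Vectorized inner loop for the send-at-time-0 families (k alerts at 0)."""
    n_inner = delays.shape[0]
    if k == 0:
        base = float(survival_prob(cfg.t_ems_min, cfg.t_ems_min, survival_model))
        return OuterSummary(0.0, base, 0.0, 0.0, 0.0, n_inner)
    acc = replies[:, :k] == Reply.ACCEPT
    arrivals = np.where(acc, delays[:, :k] + travel_s[:k], np.inf)
    first = arrivals.min(axis=1)
    n_arr = acc.sum(axis=1)
    sp = survival_prob(_t_cpr_min(first, cfg), cfg.t_ems_min, survival_model)
    return OuterSummary(
        coverage=float(np.mean(first <= cfg.coverage_threshold_s)),
        mean_survival=float(np.mean(sp)),
        mean_alerts=float(k),
        mean_redundant=float(np.mean(np.maximum(n_arr - 1, 0))),
        frac_two_plus=float(np.mean(n_arr >= 2)),
        n_inner=n_inner,
    )


def run_policy(
    spec: PolicySpec,
    cfg: SimConfig,
    behavior: BehaviorModel,
    disk: DiskConfig,
    speed_model: SpeedModel = DEFAULT_SPEED_MODEL,
    survival_model: SurvivalModel = DEFAULT_SURVIVAL_MODEL,
    stream_key: int | None = None,
    raw_sink=None,
) -> list[OuterSummary]:
    """Run the nested Monte Carlo for one policy and density.

    Returns one :class:`OuterSummary` (inner means) per outer replication.
    ``stream_key`` overrides the per-policy random stream; pass the same key
    to several calls to couple their draws (common random numbers).
    ``raw_sink``, if given, is called with
    ``(outer_rep, inner_rep, IncidentResult)`` for every incident.
    """
    speed_model.validate_for_radius(disk.radius_m)
    if stream_key is None:
        stream_key = policy_stream_key(spec, disk)
    n = disk.n_volunteers
    vector_family = spec.family in ("send_all", "send_n1") and raw_sink is None

    summaries: list[OuterSummary] = []
    for outer in range(cfg.n_outer):
        rng = _outer_rng(cfg, stream_key, outer)
        distances = sample_distances(disk, rng)
        travel_s = 60.0 * travel_time_min(distances, speed_model) if n else np.empty(0)
        delays, replies = behavior.draw(rng, (cfg.n_inner, n))

        if vector_family:
            k = n if spec.family == "send_all" else min(spec.n1, n)
            summaries.append(
                _summarize_send(k, delays, replies, travel_s, cfg, survival_model)
            )
            continue

        results = [
            _incident_from_row(spec, delays[i], replies[i], travel_s, cfg, survival_model)
            for i in range(cfg.n_inner)
        ]
        if raw_sink is not None:
            for i, res in enumerate(results):
                raw_sink(outer, i, res)
        summaries.append(
            OuterSummary(
                coverage=float(np.mean([r.covered for r in results])),
                mean_survival=float(np.mean([r.survival_prob for r in results])),
                mean_alerts=float(np.mean([r.n_alerts for r in results])),
                mean_redundant=float(
                    np.mean([max(r.n_arrivals - 1, 0) for r in results])
                ),
                frac_two_plus=float(np.mean([r.n_arrivals >= 2 for r in results])),
                n_inner=cfg.n_inner,
            )
        )
    return summaries


def evaluate_policy(
    spec: PolicySpec,
    cfg: SimConfig,
    behavior: BehaviorModel,
    disk: DiskConfig,
    speed_model: SpeedModel = DEFAULT_SPEED_MODEL,
    survival_model: SurvivalModel = DEFAULT_SURVIVAL_MODEL,
    stream_key: int | None = None,
):
    """Run a policy and aggregate into a labelled :class:`outcomes.KpiRow`."""
    summaries = run_policy(
        spec, cfg, behavior, disk, speed_model, survival_model, stream_key
    )
    return aggregate(summaries, cfg, label=spec.label)
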