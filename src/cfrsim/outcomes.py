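"""Survival conversion and KPI aggregation.

Survival to hospital discharge is modelled as a logistic function of the
time to first CPR (T_CPR) and the time to ambulance arrival (T_EMS), both in
minutes from collapse:

    survival(T_CPR, T_EMS) = 1 / (1 + exp(b0 + b_cpr * T_CPR
                                          + b_ems * (T_EMS - T_CPR)))

with b0 = 0.04, b_cpr = 0.3 and b_ems = 0.14 per minute (the Waalewijn et
al. regression).  Because b_cpr > b_ems, survival strictly decreases as CPR
is delayed at a fixed ambulance time.  This formula is sometimes transcribed
as its complement ``1 - (1 + exp(...))^-1``, which would make survival
*increase* with the CPR delay and is inconsistent with the no-volunteer
baseline of about 98 expected survivors per year (probability 0.019 at
T_CPR = T_EMS = 13 min x 5,141 annual arrests); the complement is available
behind a flag for auditing only.

Five KPIs summarise a policy: coverage (fraction of incidents with a
volunteer arrival within 5 min of activation), expected survivors per year,
mean alerts per incident, mean redundant arrivals (volunteers arriving after
the first), and the fraction of incidents with 2+ arrivals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import DiskConfig

__all__ = [
    "SurvivalModel",
    "DEFAULT_SURVIVAL_MODEL",
    "KpiRow",
    "survival_prob",
    "aggregate",
    "density_of",
]


@dataclass(frozen=True)
class SurvivalModel:
    """Logistic survival curve coefficients (per-minute log-odds slopes)."""

    beta0: float = 0.04
    beta_cpr_per_min: float = 0.3
    beta_ems_per_min: float = 0.14
    #: audit-only: return the complement (survival increasing in T_CPR)
    complement: bool = False

    def __post_init__(self) -> None:
        if not (self.beta_cpr_per_min > self.beta_ems_per_min > 0):
            raise ValueError(
                "need beta_cpr > beta_ems > 0 for survival to decrease with CPR delay"
            )


DEFAULT_SURVIVAL_MODEL = SurvivalModel()


def survival_prob(t_cpr_min, t_ems_min, model: SurvivalModel = DEFAULT_SURVIVAL_MODEL):
    """Probability of survival to hospital discharge.

    Accepts scalars or arrays; requires 0 <= t_cpr_min <= t_ems_min (the
    engine truncates T_CPR at T_EMS before calling).
    """
    t_cpr = np.asarray(t_cpr_min, dtype=float)
    t_ems = np.asarray(t_ems_min, dtype=float)
    if np.any(t_cpr < 0):
        raise ValueError("t_cpr_min must be >= 0")
    if np.any(t_cpr > t_ems + 1e-12):
        raise ValueError("t_cpr_min must not exceed t_ems_min (truncation contract)")
    logit = model.beta0 + model.beta_cpr_per_min * t_cpr + model.beta_ems_per_min * (
        t_ems - t_cpr
    )
    p = 1.0 / (1.0 + np.exp(logit))
    if model.complement:
        p = 1.0 - p
    return float(p) if p.ndim == 0 else p


def density_of(disk: DiskConfig) -> float:
    """Volunteer density in volunteers per square kilometre."""
    r_km = disk.radius_m / 1000.0
    return disk.n_volunteers / (math.pi * r_km**2)


@dataclass(frozen=True)
class KpiRow:
    """Aggregated KPIs for one (policy, density) cell.

    ``max_ci_halfwidth_frac`` is the maximum, over the five KPIs with a
    non-zero mean, of the 95% confidence-interval halfwidth divided by the
    mean; NaN when fewer than two outer replications were run.
    """

    policy: str
    coverage: float
    survivors_per_year: float
    mean_alerts: float
    mean_redundant_arrivals: float
    frac_2plus_arrivals: float
    max_ci_halfwidth_frac: float
    n_outer: int
    n_inner: int

    def as_dict(self) -> dict:
        return {
            "policy": self.policy,
            "coverage": self.coverage,
            "survivors_per_year": self.survivors_per_year,
            "n_alerts": self.mean_alerts,
            "redundant_arrivals": self.mean_redundant_arrivals,
            "frac_2plus": self.frac_2plus_arrivals,
            "max_ci_halfwidth_frac": self.max_ci_halfwidth_frac,
        }


def aggregate(outer_summaries, cfg, label: str = "") -> KpiRow:
    """Aggregate per-outer-replication inner means into one KPI row.

    The confidence interval treats the outer replications (volunteer
    location sets) as i.i.d. observations of the inner means: a two-sided
    95% Student-t interval on each KPI.  The inner (behavioral) Monte Carlo
    variance is absorbed into the inner means.
    """
    summaries = list(outer_summaries)
    m = len(summaries)
    if m == 0:
        raise ValueError("need at least one outer replication")

    cols = {
        "coverage": np.array([s.coverage for s in summaries]),
        "survival": np.array([s.mean_survival for s in summaries]),
        "alerts": np.array([s.mean_alerts for s in summaries]),
        "redundant": np.array([s.mean_redundant for s in summaries]),
        "two_plus": np.array([s.frac_two_plus for s in summaries]),
    }
    means = {k: float(v.mean()) for k, v in cols.items()}

    if m >= 2:
        tcrit = stats.t.ppf(0.975, m - 1)
        fracs = []
        for k, v in cols.items():
            if means[k] > 0:
                hw = tcrit * v.std(ddof=1) / math.sqrt(m)
                fracs.append(hw / means[k])
        max_frac = max(fracs) if fracs else math.nan
    else:
        max_frac = math.nan

    n_inner = summaries[0].n_inner
    return KpiRow(
        policy=label,
        coverage=means["coverage"],
        survivors_per_year=means["survival"] * cfg.annual_ohcas,
        mean_alerts=means["alerts"],
        mean_redundant_arrivals=means["redundant"],
        frac_2plus_arrivals=means["two_plus"],
        max_ci_halfwidth_frac=float(max_frac),
        n_outer=m,
        n_inner=n_inner,
    )
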