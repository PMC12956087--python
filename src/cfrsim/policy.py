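"""Alerting-policy families and alert scheduling.

A policy decides which volunteer to alert when, based on elapsed time and
the accept/reject replies received so far.  All policies alert volunteers in
distance order (a farther volunteer only after every closer one) and stop
sending alerts once any volunteer accepts or a 10-minute cutoff passes,
whichever comes first.

Families:

* ``send_all``  — alert every available volunteer at time 0;
* ``send_n1``   — alert the closest n1 at time 0, nothing after;
* ``keep_n2``   — alert the closest n2 at time 0 and replace each incoming
  explicit reject with one alert to the next-closest volunteer (never-seen
  alerts produce no reply, hence no replacement);
* ``batched``   — alert in fixed-size batches at a fixed interval until an
  accept, the cutoff, or pool exhaustion (the New Zealand GoodSAM setting is
  batches of 3 every 60 s).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .behavior import Reply

__all__ = [
    "PolicySpec",
    "AlertEvent",
    "enumerate_policies",
    "schedule_alerts",
    "parse_policy",
    "DEFAULT_CUTOFF_S",
]

DEFAULT_CUTOFF_S = 600.0


@dataclass(frozen=True)
class PolicySpec:
    """One alerting policy: a family tag plus its parameters."""

    family: str
    n1: int | None = None
    n2: int | None = None
    batch_size: int | None = None
    batch_interval_s: float | None = None
    cutoff_s: float = DEFAULT_CUTOFF_S

    def __post_init__(self) -> None:
        if not self.cutoff_s > 0:
            raise ValueError("cutoff_s must be > 0")
        if self.family == "send_all":
            pass
        elif self.family == "send_n1":
            if self.n1 is None or self.n1 < 1:
                raise ValueError("send_n1 requires n1 >= 1")
        elif self.family == "keep_n2":
            if self.n2 is None or self.n2 < 1:
                raise ValueError("keep_n2 requires n2 >= 1")
        elif self.family == "batched":
            if self.batch_size is None or self.batch_size < 1:
                raise ValueError("batched requires batch_size >= 1")
            if self.batch_interval_s is None or not self.batch_interval_s > 0:
                raise ValueError("batched requires batch_interval_s > 0")
        else:
            raise ValueError(f"unknown policy family: {self.family!r}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def send_all(cls, cutoff_s: float = DEFAULT_CUTOFF_S) -> "PolicySpec":
        return cls("send_all", cutoff_s=cutoff_s)

    @classmethod
    def send(cls, n1: int, cutoff_s: float = DEFAULT_CUTOFF_S) -> "PolicySpec":
        return cls("send_n1", n1=n1, cutoff_s=cutoff_s)

    @classmethod
    def keep(cls, n2: int, cutoff_s: float = DEFAULT_CUTOFF_S) -> "PolicySpec":
        return cls("keep_n2", n2=n2, cutoff_s=cutoff_s)

    @classmethod
    def batched(
        cls,
        batch_size: int = 3,
        batch_interval_s: float = 60.0,
        cutoff_s: float = DEFAULT_CUTOFF_S,
    ) -> "PolicySpec":
        return cls(
            "batched",
            batch_size=batch_size,
            batch_interval_s=batch_interval_s,
            cutoff_s=cutoff_s,
        )

    nz_current = batched  # NZ GoodSAM configuration: batched(3, 60)

    # -- naming ------------------------------------------------------------
    @property
    def label(self) -> str:
        """Human-readable policy name (matches common reporting style)."""
        if self.family == "send_all":
            return "Send all at time 0"
        if self.family == "send_n1":
            return f"Send {self.n1} alerts at time 0."
        if self.family == "keep_n2":
            noun = "alert" if self.n2 == 1 else "alerts"
            return f"Keep {self.n2} {noun} active."
        if self.batch_size == 3 and self.batch_interval_s == 60.0:
            return "NZ current strategy."
        return f"Batched {self.batch_size} every {self.batch_interval_s:g} s."

    def as_string(self) -> str:
        """Compact policy syntax used by the CLI and config files."""
        if self.family == "send_all":
            return "send_all"
        if self.family == "send_n1":
            return f"send:{self.n1}"
        if self.family == "keep_n2":
            return f"keep:{self.n2}"
        return f"batched:{self.batch_size}:{self.batch_interval_s:g}"


def parse_policy(text: str, cutoff_s: float = DEFAULT_CUTOFF_S) -> PolicySpec:
    """Parse ``send_all``, ``send:<n1>``, ``keep:<n2>`` or
    ``batched:<size>:<interval_s>`` into a :class:`PolicySpec`."""
    parts = text.strip().split(":")
    try:
        if parts[0] == "send_all" and len(parts) == 1:
            return PolicySpec.send_all(cutoff_s)
        if parts[0] == "send" and len(parts) == 2:
            return PolicySpec.send(int(parts[1]), cutoff_s)
        if parts[0] == "keep" and len(parts) == 2:
            return PolicySpec.keep(int(parts[1]), cutoff_s)
        if parts[0] == "batched" and len(parts) == 3:
            return PolicySpec.batched(int(parts[1]), float(parts[2]), cutoff_s)
    except ValueError as exc:
        raise ValueError(f"invalid policy string {text!r}: {exc}") from None
    raise ValueError(f"invalid policy string {text!r}")


def enumerate_policies(cutoff_s: float = DEFAULT_CUTOFF_S) -> list[PolicySpec]:
    """The 27 evaluated policies: send-all, keep 1..10, send 1..15, NZ batched.

    The order matches the standard reporting order of the KPI tables.
    """
    return (
        [PolicySpec.send_all(cutoff_s)]
        + [PolicySpec.keep(k, cutoff_s) for k in range(1, 11)]
        + [PolicySpec.send(k, cutoff_s) for k in range(1, 16)]
        + [PolicySpec.batched(3, 60.0, cutoff_s)]
    )


@dataclass(frozen=True)
class AlertEvent:
    """One alert: which volunteer (by distance rank, 0 = closest) and when."""

    volunteer_rank: int
    alert_time_s: float


def schedule_alerts(
    spec: PolicySpec,
    n_available: int,
    view_delays,
    replies,
) -> list[AlertEvent]:
    """Resolve the alert schedule for one incident.

    ``view_delays[r]`` and ``replies[r]`` are the pre-drawn response of the
    volunteer at distance rank ``r``; a volunteer alerted at time ``t``
    replies at ``t + view_delays[r]`` (never, if the delay is infinite).
    The schedule is the fixed point of the policy's rules against this
    induced reply stream: no alert is sent at or after the first accept or
    at/after the cutoff, and ranks are always alerted in order.

    Ties are resolved conservatively toward fewer alerts: a reject arriving
    exactly at the first-accept instant spawns no replacement, and a batch
    scheduled exactly at an accept instant is not sent.
    """
    if n_available < 0:
        raise ValueError("n_available must be >= 0")
    if len(view_delays) < n_available or len(replies) < n_available:
        raise ValueError("need a response for every available volunteer")
    n = n_available
    if n == 0:
        return []
    d = np.asarray(view_delays, dtype=float)
    rep = np.asarray(replies)

    if spec.family in ("send_all", "send_n1"):
        k = n if spec.family == "send_all" else min(spec.n1, n)
        return [AlertEvent(r, 0.0) for r in range(k)]

    if spec.family == "keep_n2":
        k0 = min(spec.n2, n)
        events = [AlertEvent(r, 0.0) for r in range(k0)]
        # reply-event heap keyed (time, accept-first tie-break, rank)
        heap = [
            (float(d[r]), 0 if rep[r] == Reply.ACCEPT else 1, r)
            for r in range(k0)
            if math.isfinite(d[r])
        ]
        heapq.heapify(heap)
        first_accept = math.inf
        next_rank = k0
        while heap:
            t, _, r = heapq.heappop(heap)
            if t >= first_accept:
                break  # later replies cannot trigger alerts
            if rep[r] == Reply.ACCEPT:
                first_accept = t
            elif t < spec.cutoff_s and next_rank < n:
                events.append(AlertEvent(next_rank, t))
                if math.isfinite(d[next_rank]):
                    heapq.heappush(
                        heap,
                        (
                            t + float(d[next_rank]),
                            0 if rep[next_rank] == Reply.ACCEPT else 1,
                            next_rank,
                        ),
                    )
                next_rank += 1
        return events

    # batched
    events: list[AlertEvent] = []
    first_accept = math.inf
    next_rank = 0
    i = 0
    while next_rank < n:
        t = i * spec.batch_interval_s
        if t >= spec.cutoff_s or t >= first_accept:
            break
        stop = min(next_rank + spec.batch_size, n)
        for r in range(next_rank, stop):
            events.append(AlertEvent(r, t))
            if rep[r] == Reply.ACCEPT and math.isfinite(d[r]):
                first_accept = min(first_accept, t + float(d[r]))
        next_rank = stop
        i += 1
    return events
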