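import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfrsim.behavior import Reply
from cfrsim.policy import (
    DEFAULT_CUTOFF_S,
    AlertEvent,
    PolicySpec,
    enumerate_policies,
    parse_policy,
    schedule_alerts,
)

A, R, N = int(Reply.ACCEPT), int(Reply.REJECT), int(Reply.NOT_SEEN)


def _delays_for(replies, seen_delays):
    """Build a delay vector: finite for seen replies, inf for not-seen."""
    it = iter(seen_delays)
    return [math.inf if r == N else float(next(it)) for r in replies]


class TestEnumeration:
    def test_27_policies(self):
        specs = enumerate_policies()
        assert len(specs) == 27

    def test_family_partition(self):
        specs = enumerate_policies()
        by_family = {
            fam: [s for s in specs if s.family == fam]
            for fam in ("send_all", "send_n1", "keep_n2", "batched")
        }
        assert [len(by_family[f]) for f in ("send_all", "send_n1", "keep_n2", "batched")] == [1, 15, 10, 1]
        assert sorted(s.n1 for s in by_family["send_n1"]) == list(range(1, 16))
        assert sorted(s.n2 for s in by_family["keep_n2"]) == list(range(1, 11))
        nz = by_family["batched"][0]
        assert (nz.batch_size, nz.batch_interval_s) == (3, 60.0)

    def test_all_have_ten_minute_cutoff(self):
        assert all(s.cutoff_s == 600.0 for s in enumerate_policies())


class TestParsing:
    @pytest.mark.parametrize(
        "text,family",
        [("send_all", "send_all"), ("send:7", "send_n1"),
         ("keep:3", "keep_n2"), ("batched:3:60", "batched")],
    )
    def test_roundtrip(self, text, family):
        spec = parse_policy(text)
        assert spec.family == family
        assert parse_policy(spec.as_string()) == spec

    @pytest.mark.parametrize("bad", ["", "send", "keep:", "keep:0", "send:-2", "batched:3", "foo:1"])
    def test_invalid_strings(self, bad):
        with pytest.raises(ValueError):
            parse_policy(bad)

    def test_labels(self):
        assert PolicySpec.send_all().label == "Send all at time 0"
        assert PolicySpec.keep(7).label == "Keep 7 alerts active."
        assert PolicySpec.keep(1).label == "Keep 1 alert active."
        assert PolicySpec.send(1).label == "Send 1 alerts at time 0."
        assert PolicySpec.batched(3, 60.0).label == "NZ current strategy."


class TestSendFamilies:
    def test_send_all_alerts_everyone_at_zero(self):
        replies = [R] * 10
        ev = schedule_alerts(PolicySpec.send_all(), 10, _delays_for(replies, [5] * 10), replies)
        assert ev == [AlertEvent(r, 0.0) for r in range(10)]

    def test_send_n1_pool_exhaustion(self):
        replies = [N] * 5
        ev = schedule_alerts(PolicySpec.send(7), 5, _delays_for(replies, []), replies)
        assert len(ev) == 5 and all(e.alert_time_s == 0.0 for e in ev)

    def test_no_volunteers_no_alerts(self):
        assert schedule_alerts(PolicySpec.send_all(), 0, [], []) == []


class TestKeepActive:
    def test_replacement_hand_trace(self):
        # rank 0 rejects 30 s after its t=0 alert; its replacement (rank 1,
        # alerted at 30) accepts 45 s later, i.e. at 75 s.
        replies = [R, A]
        ev = schedule_alerts(PolicySpec.keep(1), 2, [30.0, 45.0], replies)
        assert ev == [AlertEvent(0, 0.0), AlertEvent(1, 30.0)]

    def test_chained_replacements(self):
        replies = [R, R, A]
        ev = schedule_alerts(PolicySpec.keep(1), 3, [10.0, 20.0, 5.0], replies)
        assert ev == [AlertEvent(0, 0.0), AlertEvent(1, 10.0), AlertEvent(2, 30.0)]

    def test_not_seen_never_triggers_replacement(self):
        replies = [N, A]
        ev = schedule_alerts(PolicySpec.keep(1), 2, [math.inf, 5.0], replies)
        assert ev == [AlertEvent(0, 0.0)]

    def test_reject_at_or_after_cutoff_spawns_nothing(self):
        replies = [R, A]
        ev = schedule_alerts(PolicySpec.keep(1), 2, [DEFAULT_CUTOFF_S, 1.0], replies)
        assert ev == [AlertEvent(0, 0.0)]

    def test_reject_at_first_accept_instant_spawns_nothing(self):
        # accept and reject both at t=40: stop rule wins the tie
        replies = [A, R, R]
        ev = schedule_alerts(PolicySpec.keep(2), 3, [40.0, 40.0, 1.0], replies)
        assert ev == [AlertEvent(0, 0.0), AlertEvent(1, 0.0)]

    def test_no_replacement_after_first_accept(self):
        replies = [A, R, R]
        ev = schedule_alerts(PolicySpec.keep(2), 3, [10.0, 50.0, 1.0], replies)
        assert len(ev) == 2


class TestBatched:
    def test_full_run_without_accept(self):
        # 3 per minute from t=0; cutoff at 600 s means batches at 0..540 only
        replies = [N] * 40
        ev = schedule_alerts(PolicySpec.batched(3, 60.0), 40, _delays_for(replies, []), replies)
        assert len(ev) == 30
        times = sorted({e.alert_time_s for e in ev})
        assert times == [60.0 * i for i in range(10)]
        assert max(e.alert_time_s for e in ev) == 540.0

    def test_stops_at_first_accept(self):
        # rank 1 (batch at t=0) accepts at 70 s: the t=120 batch is not sent
        replies = [R, A] + [R] * 10
        delays = [5.0, 70.0] + [1000.0] * 10
        ev = schedule_alerts(PolicySpec.batched(2, 60.0), 12, delays, replies)
        assert [e.alert_time_s for e in ev] == [0.0, 0.0, 60.0, 60.0]

    def test_batch_exactly_at_accept_instant_not_sent(self):
        replies = [A] + [R] * 5
        delays = [60.0] + [1000.0] * 5
        ev = schedule_alerts(PolicySpec.batched(1, 60.0), 6, delays, replies)
        assert [e.alert_time_s for e in ev] == [0.0]

    def test_pool_exhaustion(self):
        replies = [N] * 4
        ev = schedule_alerts(PolicySpec.batched(3, 60.0), 4, _delays_for(replies, []), replies)
        assert len(ev) == 4


# ---------------------------------------------------------------------------
# property tests over random response tables


@st.composite
def response_tables(draw, max_n=12):
    n = draw(st.integers(0, max_n))
    replies = draw(st.lists(st.sampled_from([A, R, N]), min_size=n, max_size=n))
    delays = [
        math.inf if r == N else draw(st.floats(0.0, 900.0, allow_nan=False))
        for r in replies
    ]
    return n, delays, replies


def _specs_for(n):
    return (
        [PolicySpec.send_all(), PolicySpec.batched(3, 60.0)]
        + [PolicySpec.send(k) for k in (1, 3, max(n, 1))]
        + [PolicySpec.keep(k) for k in (1, 2, max(n, 1))]
    )


@settings(max_examples=200, derandomize=True, deadline=None)
@given(response_tables())
def test_schedule_invariants(table):
    """Alerted ranks form a prefix of the distance order; alert times are
    in [0, cutoff) and never at/after the first accept decision."""
    n, delays, replies = table
    for spec in _specs_for(n):
        events = schedule_alerts(spec, n, delays, replies)
        ranks = [e.volunteer_rank for e in events]
        assert ranks == list(range(len(ranks)))  # prefix, in order
        for e in events:
            assert 0.0 <= e.alert_time_s < spec.cutoff_s
            # an alert at time t is only blocked by accepts from volunteers
            # alerted strictly before t (a same-instant batch member's own
            # instant accept cannot block its own batch)
            blocking = min(
                (e2.alert_time_s + delays[e2.volunteer_rank]
                 for e2 in events
                 if replies[e2.volunteer_rank] == A
                 and e2.alert_time_s < e.alert_time_s),
                default=math.inf,
            )
            assert e.alert_time_s < blocking or e.alert_time_s == 0.0
        # alert times are non-decreasing in rank
        times = [e.alert_time_s for e in events]
        assert times == sorted(times)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(response_tables())
def test_policy_equivalences(table):
    """send n1=n, keep n2=n and send_all produce identical schedules."""
    n, delays, replies = table
    if n == 0:
        return
    ev_all = schedule_alerts(PolicySpec.send_all(), n, delays, replies)
    ev_send = schedule_alerts(PolicySpec.send(n), n, delays, replies)
    ev_keep = schedule_alerts(PolicySpec.keep(n), n, delays, replies)
    assert ev_all == ev_send == ev_keep


@settings(max_examples=200, derandomize=True, deadline=None)
@given(response_tables())
def test_alert_count_monotone_in_policy_size(table):
    """For a fixed response table, alert counts are non-decreasing in n1/n2."""
    n, delays, replies = table
    send_counts = [len(schedule_alerts(PolicySpec.send(k), n, delays, replies))
                   for k in range(1, n + 2)]
    keep_counts = [len(schedule_alerts(PolicySpec.keep(k), n, delays, replies))
                   for k in range(1, n + 2)]
    assert send_counts == sorted(send_counts)
    assert keep_counts == sorted(keep_counts)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(response_tables())
def test_keep_dominates_send_same_size(table):
    """keep n sends at least as many alerts as send n, alerted set is a superset."""
    n, delays, replies = table
    for k in (1, 2, 5):
        ev_send = schedule_alerts(PolicySpec.send(k), n, delays, replies)
        ev_keep = schedule_alerts(PolicySpec.keep(k), n, delays, replies)
        assert len(ev_keep) >= len(ev_send)
        # shared ranks are alerted no later under keep than under send (all t=0)
        keep_times = {e.volunteer_rank: e.alert_time_s for e in ev_keep}
        for e in ev_send:
            assert keep_times[e.volunteer_rank] == e.alert_time_s == 0.0
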