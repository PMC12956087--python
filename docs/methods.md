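# Methods

## Scope and structure

`cfrsim` simulates the response of smartphone-alerted community first
responders (CFRs) to out-of-hospital cardiac arrest (OHCA) and scores
alerting policies on survival, coverage, alert volume and redundant
arrivals. The model is deliberately minimal: one incident at a time, a
circular dispatch region, straight-line distances, a constant ambulance
time, and response behavior summarized by the joint law of a volunteer's
view delay and reply. Everything a policy can react to — elapsed time and
explicit accepts/rejects — is represented; everything else (road networks,
AED retrieval, per-volunteer history, simultaneous incidents) is out of
scope.

## Incident timeline

All times are seconds unless noted. Collapse happens at −(witness + triage)
relative to CFR-system activation ("time 0"): a 60 s witness delay (collapse
to emergency call) and a 124 s triage delay (call to activation). Alerts are
sent at policy-determined times ≥ 0. A volunteer alerted at `a` with view
delay `v` decides at `a + v`; an accepter then travels and arrives at
`a + v + travel`. The ambulance arrives at `T_EMS` = 13 minutes after
collapse regardless of the volunteer process. Time to CPR is

    T_CPR = min(witness + triage + first volunteer arrival, T_EMS)

so an incident with no volunteer arrival has `T_CPR = T_EMS` exactly, which
is the survival floor.

## Geometry

Volunteers are independent uniform points in a disk of radius `R` (default
1,000 m) centred on the patient. Only distances matter (the patient sits at
the centre), so sampling uses the radial inverse CDF `r = R·√U` and angles
are never generated. Distances are sorted ascending once per location set;
the sort order *is* the alert priority, implementing the rule that a farther
volunteer is alerted only after every closer one.

Travel speed in km/h is linear in distance: `y(x) = intercept + slope·x`
with defaults 1.83 km/h and 0.0108 km/h per metre, giving
`travelTime(x) = 60x / (1830 + 10.8x)` minutes — 4.75 min at 1 km. The
model is not clamped: with the defaults the speed is positive everywhere,
and configurations whose speed would turn non-positive inside the disk are
rejected before a run starts. `fit_speed_model` re-estimates the law from
`(distance, travel time)` observations the way the defaults were derived:
drop zero travel times, bin into 100-m blocks, drop the 0–100 m block
(unreliable GPS at short range), take each block's median speed, and run
unweighted OLS of median speed on the block midpoint. Block medians are
unweighted because block counts are a property of the particular log, not
of the speed law; the midpoint represents a block since no other
representative is obviously better and the choice moves the fit by less
than the binning error.

## Response behavior

A volunteer's response is a joint draw of `(view_delay, reply)` with reply ∈
{accept, reject, not-seen}; not-seen ⇔ infinite view delay, and an infinite
delay can never produce an arrival. Replies are i.i.d. across volunteers
and alerts — no per-volunteer heterogeneity, no time-of-day effects, and no
en-route drop-out after acceptance (accept-then-drop records count as
accepts when a log is loaded).

**Bootstrap mode** resamples whole records uniformly with replacement,
preserving the delay–reply dependence exactly. **Synthetic mode** emulates
the GoodSAM New Zealand log, whose record-level data are not publicly
deposited; only the category counts (5,208 accepts incl. drop-outs, 7,925
rejects, 16,174 not seen of 29,307), the 17.77% marginal acceptance rate,
and the qualitative shapes (right-skewed view delays, acceptance declining
with delay) are published. The generator therefore:

* draws the reply category with the published marginal probabilities;
* gives seen alerts a log-normal view delay — median 30 s (a plausible
  glance-at-phone timescale), log-sd 1.0 (right-skewed, upper tail of
  several minutes);
* accepts a seen alert with probability `sigmoid(−(a + b·z))`, where `z` is
  the standardized log delay and `b` (default 1.0) sets the decline rate;
  the intercept `a` is solved by Gauss–Hermite quadrature + Brent's method
  at model construction so the *marginal* acceptance equals the configured
  rate exactly, whatever shape parameters are chosen.

All shape parameters are exposed in `SyntheticBehaviorParams` and were
chosen once, before any downstream comparison. Consequences for validation:
KPIs that depend only on the acceptance marginal (alert counts under
send-at-time-0 policies, redundant arrivals, 2+ fractions under send-all)
are reproduced faithfully; KPIs that depend on the delay *timing* (coverage,
survival, keep/batched alert counts) are internally consistent but not
calibrated to the unpublished empirical delay distribution, and the test
suite makes claims only of the first kind about real-world values.

## Policies and scheduling

Four families (27 policies): send-all, send-n1 (n1 = 1..15), keep-n2
(n2 = 1..10), and the batched NZ policy (3 alerts at t = 0 and 3 more each
minute). Global stopping rules: no alert at or after the first accept, none
at or after the 10-minute cutoff, and none once the pool is exhausted.

`schedule_alerts` resolves the schedule for one incident from the per-rank
pre-drawn responses. Because a volunteer's decision time is their own alert
time plus their own delay, the schedule/reply fixed point is well defined
and is computed by a single chronological event loop (keep-n2: a heap of
pending decisions; batched: a scan over batch instants). Tie-breaks are
conservative toward fewer alerts: a reject landing exactly at the first
accept instant spawns no replacement, and a batch scheduled exactly at an
accept instant is not sent. A volunteer's *own* instant accept cannot block
the batch that alerts them. Never-seen alerts produce no reply event and
hence never trigger a keep-n2 replacement. The NZ policy's stop condition
is evaluated continuously (an accept between batch instants cancels later
batches), which is the natural reading of "until one volunteer accepts";
batch-instant-only evaluation would only add alerts in the window between
an accept and the next instant.

## Nested Monte Carlo and seeding

The design is nested: `n_outer` volunteer location sets (default 1,000),
each evaluated under `n_inner` joint response draws (default 10,000). Per
outer replication the engine draws one full `n_inner × n` response table;
send-at-time-0 policies are then resolved vectorially (they reduce to
row-wise minima over accepters), other families incident by incident through
the event loop, and a dual-route test pins the two paths to each other.
Arrivals are counted for every alerted accepter with no time window — even
after the ambulance or another volunteer — because redundancy measures
volunteer burden, not clinical benefit; only survival is truncated at
`T_EMS`. (Published send-all redundancy at n = 100 sits ~0.2% below the
no-window binomial closed form; no window choice explains the gap, so none
is imposed, and an arrival-window option is left to configuration rather
than silently absorbed.)

Randomness: every stream is a `numpy` `SeedSequence(master_seed,
spawn_key=(stream_key, outer_rep))`, with `stream_key` a CRC-32 of the
policy string and density. Runs are bit-reproducible, adding policies does
not perturb existing streams, and passing one shared `stream_key` to several
`run_policy` calls yields common random numbers (identical location sets
and response tables) for sharpened paired comparisons. The default is
independent streams per policy, matching a design in which each policy is
simulated on its own draws.

## Outcomes

Five KPIs per (policy, density): coverage = P(first arrival ≤ 300 s after
activation, inclusive boundary); expected survivors per year = mean survival
probability × 5,141 annual OHCAs (the New Zealand count); mean alerts; mean
redundant arrivals = E[max(arrivals − 1, 0)]; and P(2+ arrivals).
Uncertainty is reported as the maximum over the five KPIs of a two-sided
95% Student-t halfwidth over the outer-replication inner means, divided by
the KPI mean, skipping zero-mean KPIs. 95% is a convention choice; the
inner-sampling variance is deliberately absorbed into the inner means so
the interval reflects location uncertainty at the stated inner precision.

The survival curve is `1/(1 + exp(0.04 + 0.3·T_CPR + 0.14·(T_EMS −
T_CPR)))` with times in minutes. The curve is occasionally transcribed with
a leading "1 −", which would make survival *increase* with CPR delay; that
variant contradicts the no-volunteer baseline (≈ 0.019 probability, 98
expected survivors/year at T_CPR = T_EMS = 13) and is provided only behind
`SurvivalModel(complement=True)` for auditing. The coefficient constraint
`beta_cpr > beta_ems > 0` is enforced so survival is strictly decreasing in
CPR delay.

## Problem sizes and numerical choices

Desk-scale defaults (CLI and examples) are 50 outer × 200 inner
replications; the full 1,000 × 10,000 design is behind `--paper-scale` /
`SimConfig` defaults. The acceptance script uses 50 × 2,000 (100,000
incidents per density), at which the send-all redundancy KPIs carry Monte
Carlo standard errors well under 1%. Stochastic tests assert within 3
standard errors computed from the outer replications. Degenerate inputs:
zero volunteers yields a valid incident (no alerts, survival floor); a
single outer replication yields NaN confidence halfwidths; empty record
sets, non-positive speeds inside the disk, unsorted distance vectors and
inconsistent delay/reply pairs are rejected at the boundary.

## Known limitations

* Coverage and survival levels inherit the synthetic view-delay
  assumptions wherever the real response log is unavailable.
* Constant `T_EMS` (no ambulance stochasticity), single incident at a time,
  no volunteer exhaustion across incidents, uniform density within the
  disk — a real region mixes densities and would need a density mixture.
* The survival curve assumes volunteer CPR quality equals that of the
  population behind the curve's estimation.
* Accept-then-drop behavior en route is not modelled; redundant-arrival
  counts are therefore upper bounds on actual on-scene crowding.
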