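# cfrsim

Monte Carlo evaluation of **phased alerting policies** for community first
responder (CFR) systems — smartphone-dispatched volunteers sent to
out-of-hospital cardiac arrests (OHCA).

A dispatch policy decides *which* nearby volunteer to alert *when*. Alerting
everyone maximises the chance of fast CPR but floods volunteers with alerts
and puts several responders on scene for one patient, which feeds long-run
volunteer fatigue. Phased policies (batches, or replacing each reject with a
fresh alert) trade a little response time for far less volunteer burden.
`cfrsim` quantifies that trade-off so a CFR system manager can compare
policies before changing a live system.

## The model

For each simulated arrest, `n` volunteers are placed uniformly at random in
a 1-km disk around the patient (distance CDF `P(D ≤ d) = (d/R)²`) and sorted
by distance; policies always alert closer volunteers first. Each alerted
volunteer draws a joint *(view delay, reply)* — accept, reject, or never
seen (infinite delay) — either bootstrapped from a historical response log
or from a synthetic generator calibrated to the GoodSAM New Zealand log
(29,307 alerts; 17.77% accepted, 27.0% rejected, 55.2% never seen;
acceptance declining with view delay). An accepter travels at a
distance-dependent speed

```
speed(x) = 1.83 + 0.0108·x  km/h   ⇒   travelTime(x) = 60x / (1830 + 10.8x)  minutes
```

and arrives at *alert time + view delay + travel time*. No alerts are sent
after the first accept or after a 10-minute cutoff. Survival to hospital
discharge follows the Waalewijn logistic curve in the time to first CPR
(`T_CPR`, minutes from collapse, = 60 s witness delay + 124 s triage delay +
first arrival, capped at the ambulance time `T_EMS` = 13 min):

```
survival(T_CPR, T_EMS) = 1 / (1 + exp(0.04 + 0.3·T_CPR + 0.14·(T_EMS − T_CPR)))
```

Policy families (27 policies total): **send all** at time 0; **send n1**
(n1 = 1..15) at time 0; **keep n2 active** (n2 = 1..10: replace every
incoming reject with one alert to the next-closest volunteer); and the
**NZ current policy** (3 alerts at time 0 plus 3 more each minute). Five
KPIs per policy: coverage (arrival within 5 min of activation), expected
survivors per year (mean survival × 5,141 annual OHCAs), mean alerts per
incident, mean redundant arrivals, and the fraction of patients with 2+
arrivals. The nested design (outer replications = volunteer location sets,
inner replications = response draws) yields Student-t confidence halfwidths
over the outer means.

## Worked example

`examples/compare_policies.py` compares the NZ batched policy with keep-7,
send-6 and send-all for 30 volunteers within 1 km (desk scale, 50 × 200
replications):

```
policy                       coverage  surv/yr  alerts  redund     2+
NZ current strategy.            0.490    210.9    7.05   0.255  0.231
Keep 7 alerts active.           0.750    228.1    7.97   0.562  0.407
Send 6 alerts at time 0.        0.666    210.3    6.00   0.368  0.281
Send all at time 0              0.982    248.0   30.00   4.340  0.978
```

Send-all dominates on survival (248 expected survivors/year versus the
no-volunteer floor of 98) but sends 30 alerts and puts ~4 redundant
volunteers on scene per arrest; keep-7 recovers most of the survival gain
at a quarter of the alert volume. Absolute coverage/survival levels depend
on the configured view-delay distribution (see `docs/methods.md`); the
alert-volume and redundancy columns depend only on the acceptance rate.

The same experiment from the shell:

```
cfrsim tables --n 10 --n 30 --n 100 --seed 1 --out-dir results/
cfrsim run --policy keep:7 --policy batched:3:60 --n 30 --seed 1 --out-dir results/
cfrsim make-fixture --n-records 29307 --out fixtures/log.csv
cfrsim fit-speed --input travel_log.csv
```

Other examples: `single_incident.py` (one incident traced end to end),
`fit_speed_model.py` (recovering the speed law from noisy travel records),
`synthetic_response_log.py` (generating and bootstrapping a response log).

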