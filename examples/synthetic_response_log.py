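"""Generate, save and reload a synthetic volunteer response log.

The synthetic generator emulates the GoodSAM New Zealand alert log:
reply-category marginals matching the recorded counts (17.77% accept,
27.0% reject, 55.2% not seen), right-skewed view delays for seen alerts,
and an acceptance probability that declines with view delay.
"""

import math
import tempfile
from pathlib import Path

import numpy as np

from cfrsim import Reply, acceptance_rate, load_records, make_synthetic_log, write_log

records = make_synthetic_log(29_307, rng_seed=0)

path = Path(tempfile.mkdtemp()) / "synthetic_log.csv"
write_log(records, path)
reloaded = load_records(path)
assert reloaded == records

n = len(reloaded)
counts = {r: sum(rec.reply is r for rec in reloaded) for r in Reply}
seen = [rec.view_delay_s for rec in reloaded if math.isfinite(rec.view_delay_s)]
print(f"wrote and reloaded {n} records from {path}")
print(f"accepted: {counts[Reply.ACCEPT]}  rejected: {counts[Reply.REJECT]}  "
      f"not seen: {counts[Reply.NOT_SEEN]}")
print(f"acceptance rate: {acceptance_rate(reloaded):.4f}  (GoodSAM NZ: 0.1777)")
print(f"median view delay of seen alerts: {np.median(seen):.1f} s")
print()
print("Bootstrap these records with BehaviorModel.bootstrap(records) to drive")
print("the simulator, exactly as one would with a real response log.")
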