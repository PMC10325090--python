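"""What a non-contractile actin fiber does to an adhesion.

Compares two 300-s runs at k = 0.6 pN/nm, no myosin force: one without a
fiber and one with a 300-nm fiber at full bundling (every free integrin under
the strip activates at 3/s instead of 1/s).  Prints the stabilisation and
elongation readouts.
"""

import numpy as np

from adhesim import run, validate_params
from adhesim.observables import (angle_series, density_profile, event_rates,
                                 ligated_fraction)

WINDOW = (100.0, 300.0)
runs = {}
for tag, extra in (("no fiber", {}),
                   ("fiber   ", {"fiber_present": True, "P_bundling": 1.0})):
    p = validate_params({"seed": 2, "k_sub": 0.6, "t_total": 300.0, **extra})
    runs[tag] = run(p)

print(f"{'':10s} {'ligated %':>10s} {'binds/s':>9s} {'bound time':>11s} {'angle':>7s}")
for tag, traj in runs.items():
    pct = ligated_fraction(traj, WINDOW)[2]
    rate = event_rates(traj.events, WINDOW, 300)[0]
    tot = traj.total_ligated_time.mean()
    ang = angle_series(traj, WINDOW)[2]
    print(f"{tag:10s} {pct:10.1f} {rate:9.1f} {tot:9.1f} s {ang:6.1f}d")

prof = density_profile(runs["fiber   "], n_bins=20, window=WINDOW)
centers = np.linspace(-0.475, 0.475, 20)
inside = np.abs(centers) <= 0.15
print(f"\nligated density inside the strip : {prof[inside].mean():.2f} % per bin")
print(f"ligated density outside          : {prof[~inside].mean():.2f} % per bin")
print("\nThe fiber raises binding, total bound time and ligated density under")
print("the strip, and pulls the adhesion's principal axis toward the fiber")
print("axis (small angle) -- stabilisation and elongation without any myosin.")
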