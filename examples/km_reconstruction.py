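"""Emulated digitization of a Kaplan-Meier figure and pseudo-IPD recovery.

Published survival figures are often the only data source for a
cost-effectiveness model: the curve is digitized by hand, pseudo
individual-patient data are reconstructed from the read-off coordinates,
and parametric models are refitted.  This example runs that whole loop with
a known ground truth so the information loss can be seen directly.
"""

from psmcea import (
    DistributionSpec,
    digitize_curve,
    fit_mle,
    km_estimate,
    pseudo_ipd,
    simulate_ipd,
)

truth = DistributionSpec("loglogistic", {"shape": 2.558, "scale": 17.166})
ipd = simulate_ipd(truth, n=400, censor_rate=0.0, admin_cutoff=60.0, seed=17)
km = km_estimate(ipd)
print(f"trial-like sample: n={len(ipd)}, KM curve with {len(km.times)} steps")

digitized = digitize_curve(km, grid_step=0.5, jitter_sd=0.005, seed=17)
print(f"digitized on a 0.5-month grid with sd=0.005 read-off noise "
      f"({len(digitized.times)} points)")

reconstructed = pseudo_ipd(digitized, n_assumed=400)
fit = fit_mle(reconstructed, "loglogistic")
shape = fit.spec.params["shape"]
scale = fit.spec.params["scale"]
print(f"\nrefit on pseudo-IPD: shape={shape:.3f} (truth 2.558, "
      f"{100 * (shape / 2.558 - 1):+.1f}%), scale={scale:.3f} "
      f"(truth 17.166, {100 * (scale / 17.166 - 1):+.1f}%)")
print("Recovery within a few percent shows the digitization pathway "
      "preserves the curve shape; the residual error is what any model "
      "built on digitized figures inherits.")
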