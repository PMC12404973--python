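"""Parametric survival fitting with AIC/BIC model selection.

Simulates censored individual-patient data from a known log-logistic truth
(the shape the overall-population OS fit takes), fits all eight supported
families by maximum likelihood, and ranks them by information criteria —
the same workflow used to pick extrapolation curves from digitized
Kaplan-Meier data.
"""

from psmcea import DistributionSpec, Family, fit_mle, select_best, simulate_ipd

truth = DistributionSpec("loglogistic", {"shape": 2.558, "scale": 17.166})
data = simulate_ipd(truth, n=2000, censor_rate=0.2, admin_cutoff=60.0, seed=1)
print(f"simulated n={len(data)}, events={data.n_events} "
      f"(truth: log-logistic shape 2.558, scale 17.166)\n")

fits = []
print(f"{'family':20s} {'loglik':>10s} {'AIC':>10s} {'BIC':>10s}")
for family in Family:
    fit = fit_mle(data, family)
    fits.append(fit)
    print(f"{family.value:20s} {fit.loglik:10.1f} {fit.aic:10.1f} {fit.bic:10.1f}")

best = select_best(fits, "aic")
params = ", ".join(f"{k}={v:.3f}" for k, v in best.spec.params.items())
print(f"\nbest by AIC: {best.spec.family.value} ({params})")
print("Lower AIC/BIC is better; the generating family (or a close "
      "neighbour that nests it) should win at this sample size.")
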