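"""Round trip: simulate a cohort from the model, refit, compare.

Generates the study-sized synthetic cohort (18 subjects, RR sampled
every minute for 24 h, long-memory AR(180) residuals), fits the cosinor
regression with cluster-robust (subject-level) inference, fits the AR
residual process, and compares the estimates with the generating truth.
"""

import warnings

import numpy as np

from cardiocirc import fit_ar_residuals, fit_circadian_model, make_minute_cohort

series, manifest = make_minute_cohort(seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fit_circadian_model(series)

true = manifest.coefficients.as_array()
ci = fit.conf_int(0.95)
print(f"{'term':8s} {'true':>9s} {'estimate':>9s} {'95% CI':>22s}")
for term, t in zip(fit.terms, true):
    est = fit.params[term]
    lo, hi = ci.loc[term, "low"], ci.loc[term, "high"]
    mark = "" if lo <= t <= hi else "  <- outside CI"
    print(f"{term:8s} {t:9.4f} {est:9.4f}   [{lo:8.4f}, {hi:8.4f}]{mark}")

print(f"\nsigma: true {manifest.coefficients.sigma:.3f}, "
      f"estimated {fit.sigma:.4f}")
d = fit.diagnostics
print(f"fit quality: R2(log) = {d['r_squared_log']:.3f}, "
      f"RMSE = {d['rmse_ms']:.1f} ms, MAPE = {d['mape_percent']:.1f}%")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ar = fit_ar_residuals(fit.residuals_by_subject().values(), order=180)
print(f"AR(180) residual fit: innovation SD tau = {ar.tau:.4f} "
      f"(generating value {manifest.ar.tau})")
print("\nEach row shows one regression coefficient recovered from data the")
print("model itself generated; each CI covers its truth ~95% of the time.")
print("Misses cluster: with 18 subjects the intercept/age/age^2 columns are")
print("nearly collinear, so one unlucky cohort can push several related")
print("terms out together (this seed is such a cohort - try another).")
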