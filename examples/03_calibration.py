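"""Fit the four-parameter VOD-to-AGC curve and convert indices to carbon.

Generates (index, reference AGC) pairs from a known logistic curve with
5 Mg C/ha map noise, refits it with multi-start least squares, and prints
the recovered parameters with standard errors.  The curve maps an L-VOD
index (dimensionless) to above-ground carbon density (Mg C/ha), saturating
at high biomass.
"""

import numpy as np

from amazonagc import CalibrationCurve, fit_vod_agc_curve, vod_to_agc

TRUE = (170.0, 9.0, 0.45, 5.0)  # a (upper asymptote), b (slope), c, d (floor)
rng = np.random.default_rng(0)

v = rng.uniform(0.1, 0.9, 500)
agc_ref = np.asarray(CalibrationCurve(*TRUE)(v)) + rng.normal(0, 5.0, 500)
fit = fit_vod_agc_curve(v, agc_ref, index_method="mean_trend")

print("parameter   true    fitted     SE")
for name, t, e, se in zip("abcd", TRUE, fit.params, fit.standard_errors):
    print(f"   {name}      {t:7.2f}  {e:7.3f}  {se:6.3f}")
print(f"\nresidual sum of squares: {fit.rss:,.0f} on n={fit.n_fit} cells")

for vod in (0.3, 0.5, 0.7):
    print(f"index {vod:.1f} -> {float(vod_to_agc(fit, vod)):6.1f} Mg C/ha")
print("\nEach parameter lands within ~2 SE of truth; the saturating shape "
      "means a given VOD increment is worth less carbon at high biomass.")
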