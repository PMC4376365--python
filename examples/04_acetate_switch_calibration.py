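"""Calibrate the batch acetate-switch model from synthetic culture data.

The two-population batch model tracks glucose-consuming and
acetate-consuming biomass exchanging members through concentration-
dependent switching rates.  Calibration is staged: growth rates from the
single-substrate cultures, consumption/production rates from their
concentration curves, switching coefficients from the mixed (diauxic)
culture.  Here the data are generated by the model itself with 1%
multiplicative noise, so the fit can be compared against known truth.
"""

from dfba3d.fixtures import default_batch_params, synthetic_batch_data
from dfba3d.regulation import calibrate_switching

truth = default_batch_params()
data = synthetic_batch_data(truth, noise_cv=0.01, seed=7)
fit = calibrate_switching(data)

print(f"{'parameter':12} {'true':>10} {'fitted':>10} {'rel err':>8}")
for name in ("g_glc", "g_ace", "v_glc", "v_ace", "eps_ace"):
    t, f = getattr(truth, name), getattr(fit, name)
    print(f"{name:12} {t:10.4g} {f:10.4g} {abs(f - t) / t:8.1%}")
for key, tr in truth.switching.transitions.items():
    fitted = fit.switching.transitions[key].alpha
    for i, (a_t, a_f, fr) in enumerate(zip(tr.alpha, fitted, tr.free)):
        if fr and a_t != 0:
            label = f"alpha[{i}] {key[0]}->{key[1]}"
            print(f"{label:12} {a_t:10.4g} {a_f:10.4g} "
                  f"{abs(a_f - a_t) / abs(a_t):8.1%}")
print("\n(g in 1/hr; v, eps in mol per gDwt/l per hr; alpha in units making"
      "\n the switching rate 1/s at molar concentrations)")
print("\nThe linear rates are tightly determined; the interaction term"
      "\nalpha[5] and the return rate act only during brief transients, so"
      "\ntheir estimates degrade quickly with noise — with noiseless data"
      "\nevery coefficient is recovered to < 1% (see the test suite).")
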