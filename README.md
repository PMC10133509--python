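# fluidbalance

Transfer-function based prediction of the cumulative fluid balance (CFB)
course in intensive-care patients.

## The problem

Fluid management after major (especially cardiac) surgery is steered by
the cumulative fluid balance

    CFB(t) = CFI(t) − CFL(t),

the cumulative fluid intake minus the cumulative losses since ICU
admission. Setting achievable fluid goals requires anticipating where the
CFB is heading under the current therapy — a judgement that is
time-consuming and error-prone when done by hand.

`fluidbalance` treats each patient as a discrete-time linear system: the
minute-sampled CFI series `u[k]` is the input, the CFB series `y[k]` the
output, and the patient's "fluid response" is captured by a second-order
transfer function with direct feedthrough,

    P(z) = (b0 + b1 z⁻¹) / (1 + a1 z⁻¹ + a2 z⁻²),

identified per patient and per time window from the patient's own data —
no training cohort is needed. Future intake is extrapolated with a
one-breakpoint *broken-stick* model of the observed CFI (constant intake
rate after the detected turning point), fed through `P(z)`, and the
simulated output over the next 24 h is the CFB forecast. Forecasts are
scored at horizons of 8, 12, 16, 20 and 24 h by the RMSE of the last
30 min before the horizon and by the signed endpoint error, binned into
clinically chosen tolerance bands (±0.5 … ±2.0 L).

Because real ICU fluid datasets are not public, the package includes a
seedable synthetic cohort generator (four-phase fluid trajectories —
rescue, optimization, stabilization, evacuation — plus transfer-function
ground-truth patients), so the entire pipeline is testable end to end.

## Worked example

Predict 24 h of CFB for a synthetic ground-truth patient whose CFB is
generated by a known transfer function with 0.02 L output noise:

```python
import numpy as np
from fluidbalance import generate_tf_patient, generate_windows, predict_window

gt = generate_tf_patient(noise_sd=0.02, seed=11)
window = generate_windows(gt.record, estimation_hours=48)[0]
result = predict_window(gt.record, window)

print("true coefficients:   ", np.round([*gt.true_model.b, *gt.true_model.a], 4))
m = result.model
print("estimated coefficients:", np.round([m.b0, m.b1, m.a1, m.a2], 4))
print("intake turning point:  %.0f min, post-slope %.3f mL/min"
      % (result.cfi_fit.breakpoint, 1000 * result.cfi_fit.slope2))
for h in (8, 16, 24):
    print(f"horizon {h:2d} h: RMSE {result.rmse_by_horizon[h]:.3f} L, "
          f"endpoint error {result.endpoint_error_by_horizon[h]:+.3f} L")
```

prints

```
true coefficients:    [ 0.002  0.003 -1.7    0.72 ]
estimated coefficients: [-0.2619  0.2743 -1.5996  0.6503]
intake turning point:  720 min, post-slope 1.500 mL/min
horizon  8 h: RMSE 0.011 L, endpoint error +0.015 L
horizon 16 h: RMSE 0.015 L, endpoint error -0.014 L
horizon 24 h: RMSE 0.024 L, endpoint error -0.025 L
```

The broken stick finds the intake turning point (720 min) and the
post-breakpoint rate exactly, and the 24 h forecast is within 0.03 L of
the truth. Note that individual coefficients are only weakly identified
under noise (the output-error surface is flat along near pole-zero
cancellations) while the *simulated response* — the clinically relevant
object — is accurate; with `noise_sd=0` the recovery is exact to 1e-4.

The same pipeline runs from the shell:

```sh
fluidbalance simulate   --n 618 --seed 42 --out events.csv
fluidbalance preprocess --events events.csv --out series/
fluidbalance predict    --series series/ --estimation-hours 24,48,72,96,120 --out results.csv
fluidbalance evaluate   --results results.csv --out summary/
```

`summary/` then contains `summary_rmse.csv` (weighted mean aggregated
RMSE per estimation × horizon combination), `summary_bins.csv`
(tolerance-band percentages of endpoint errors) and the corresponding
heatmap / violin / stacked-bar figures.

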