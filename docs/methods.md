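# Methods

## Data model

All computation runs on uniformly sampled cumulative series at one data
point per minute (`dt = 60 s`), in liters. Raw input is a CSV event log
(one intake or loss per row: patient, start/end timestamps, direction,
category, volume in mL, administration mode). Event timestamps are
rounded to the nearest minute and the grid is anchored at admission
(earliest documented event, floored to the minute).

Cumulative curves are built per category and summed:

* **bolus** events (short infusions, drinks, documented loss entries)
  step the cumulative curve by the full volume in the minute containing
  the start time;
* **continuous** infusions with a documented end spread the volume
  uniformly over `[start, end)` — a linear ramp of the cumulative curve,
  the only reading consistent with a physically running infusion;
* **gravity** infusions without a documented end (and any other event
  lacking one) run at 16 mL/min until the documented volume is
  exhausted, remainder in the final minute — the clinical rule of thumb
  for undocumented gravity lines;
* **urine** is documented sparsely; its cumulative curve is linearly
  interpolated between consecutive documented entries (the bladder fills
  roughly evenly), anchored at zero at admission and held constant after
  the last entry.

Every expansion conserves the documented volume to < 1e-9 L; volume that
would run past discharge is carried in the last grid step rather than
dropped. CFB = CFI − CFL exactly, elementwise.

Cohort filters: length of stay within [4, 7] days (shorter stays precede
hemodynamic stabilization; longer ones violate the four-phase trajectory
assumption), no negative volumes, and no documentation gap longer than
24 h (the operationalization of "fluid data available for the entire
stay"; configurable). Insensible losses are not modelled.

## Patient model and identification

The patient is a discrete-time LTI system from CFI to CFB:

    P(z) = (b0 + b1 z⁻¹) / (1 + a1 z⁻¹ + a2 z⁻²)

Two poles admit the physiologically possible oscillatory or unstable
responses; the direct feedthrough b0 is required because CFB is computed
from CFI, so the output reacts within the same sample. Higher orders are
supported (`orders=(n, m)`) but default to (2, 1): with the low
excitation of clinical intake profiles, more parameters overfit.

Identification minimizes the **simulation (output-error) objective**
J(θ) = Σₖ (y[k] − ŷ_θ[k])², where ŷ_θ is the free-run simulation of
P_θ from the input alone with zero initial conditions (the window's CFB
offset is reset to zero). The one-step ARX predictor is used only as a
linear initializer; the use case is multi-hour free-run forecasting, so
the simulation error is the right objective, with uniform weighting.

The search is a damped Gauss–Newton (Levenberg–Marquardt) iteration with
an analytic Jacobian from sensitivity filters: with A(z) the current
denominator, ∂ŷ/∂bᵢ = z⁻ⁱ u / A and ∂ŷ/∂aⱼ = −z⁻ʲ ŷ / A — one extra
filter pass per pole/zero order, making a window fit cost a few
milliseconds. Steps that increase the objective or destabilize the
simulation are rejected with increased damping, so the objective is
non-increasing across accepted iterates. Convergence: relative objective
decrease < 1e-10 or 100 iterations (both configurable; engineering
choices, not physiological ones).

Stability is **not** constrained — unstable fluid responses are
clinically meaningful — but pole moduli are reported, simulations abort
when |y| exceeds a 10⁶ L guard, and such windows are flagged `diverged`
and excluded from error statistics (tallied separately). If the ARX
initializer itself simulates unstably, its poles are reflected inside
the unit circle to start the search; if no finite-objective model is
found at all, the raw ARX model is returned with `converged=False`.

On noise-free data in the model class the estimator is exact (the ARX
step already is); under output noise individual coefficients are weakly
identified when the objective surface is flat along near pole-zero
cancellations, while the simulated response — what the forecast uses —
remains accurate. Tests assert both: coefficient recovery to 1e-4
noise-free, median absolute coefficient error < 0.05 at 0.05 L noise on
48 h windows.

## Intake extrapolation (broken stick)

Future CFI is unknown at prediction time. The estimation-window CFI is
summarized by a continuous two-segment linear model (hinge
parameterization y = β0 + β1 t + β2 (t − c)₊), solved by least squares
at every candidate breakpoint c on a 15-min grid excluding 10 % margins
at either window edge (margins prevent degenerate one-point segments;
the grid is configurable down to 1 min, at which the fit provably
matches an exhaustive per-sample search). Suffix-sum normal equations
make the sweep O(n); the winning candidate is re-solved on the explicit
design matrix for full precision, and near-ties resolve to the earliest
breakpoint. The extrapolated intake continues from the last **observed**
CFI value (not the fitted line's end, so the simulation input has no
jump at the junction) at rate max(slope2, 0) — cumulative intake cannot
decrease — for 24 h.

## Sliding windows and prediction

Windows start at admission and slide in 2 h steps while fully contained
in the stay; estimation times are 24/48/72/96/120 h, each followed by a
fixed 24 h prediction period. CFB *and* CFI are re-zeroed at the window
start (zero initial conditions of the transfer function require input
and output to share the zero frame). The transfer function is simulated
over the concatenated input (observed estimation CFI + extrapolated CFI)
from zero initial conditions so its internal state at the prediction
start reflects the estimation period; the final 24 h of the output is
the forecast. Prediction segments use inclusive endpoints (1441 samples;
horizon h ↦ sample 60·h).

## Error evaluation

Per window: RMSE over the 31 samples in the last 30 min before each
horizon (8–24 h), and the signed endpoint error at the horizon. Cohort
level: window RMSEs are first averaged within a patient ("aggregated
RMSE"), then combined across patients weighted by each patient's window
count — which equals the pooled per-window mean; the unweighted patient
mean is emitted alongside since the weighting convention is a choice.
Endpoint errors are binned into cumulative symmetric bands |e| ≤ 0.5,
1.0, 1.5, 2.0 L plus "> 2 L" (2 L being the clinically chosen limit of
tolerable error), and into the corresponding disjoint shells, so either
convention of reading banded-error figures is available.

## Synthetic cohorts

The generator emulates two patient families, emitted as raw event logs
in the same CSV schema the parser reads:

* **Phase-profile patients** follow the canonical four-phase fluid
  course. Length of stay is a symmetric truncated normal, 120 ± 18 h
  truncated at ±24 h (inside the 4–7 d inclusion band by construction);
  jittered weights split it into rescue/optimization/stabilization/
  evacuation with mean durations (12, 30, 42, 36) h. Mean phase intake
  rates (250, 150, 90, 70) mL/h and loss rates (60, 100, 90, 128.6)
  mL/h are calibrated so the expected end-of-stay CFB is 1.67 L; all
  per-patient jitter is mean-preserving symmetric truncated normal, so
  the cohort mean stays on target. Intake is delivered as ~6 h
  continuous infusion chunks (a configurable fraction as gravity
  infusions with missing end timestamps), plus Poisson boluses drawn
  from the phase budget; losses are sparse urine documentation (default
  every 120 min, 80 % of losses) plus periodic drainage entries.
* **Ground-truth patients** have CFB generated by a known transfer
  function from a piecewise-linear CFI, plus optional iid Gaussian
  output noise. Losses are back-derived (CFL = CFI − CFB) and clipped to
  be nondecreasing with the clip count reported; the default model
  (poles 0.9/0.8, DC gain 0.25, small feedthrough) has a monotone step
  response slower than the intake ramp, so the noise-free record needs
  no clipping and lies exactly in the model class — the basis of the
  closed-loop exactness check (endpoint error < 0.01 L at 24 h). White
  output noise does force clipping (reported), which rectifies part of
  the noise; parameter-recovery properties therefore use directly
  simulated noisy windows.

What the generator does **not** emulate: documentation errors and
missing entries beyond the gravity-infusion mechanism, re-accumulation
after evacuation, therapy changes inside the prediction window,
medication pharmacology, or any hemodynamic covariates. Passing tests
demonstrate the pipeline's correctness and its behaviour on data with
the stated statistical shape — not clinical performance.

## Problem sizes and numerical choices

The test suite runs the full pipeline on a 618-patient cohort across all
five estimation times (~34 000 windows); the acceptance script uses a
150-patient cohort with estimation times 24 h and 48 h as its default
demonstration scale. Tolerances: simulation vs. reference recursion
1e-10 L; volume conservation 1e-9 L; coefficient recovery 1e-4
(noise-free). Degenerate inputs: an all-zero regressor yields the zero
model with a `degenerate_input` flag; windows shorter than two breakpoint
candidates fall back to a single-line fit with the breakpoint at the
window midpoint; a zero-duration continuous infusion is treated as a
bolus.

## Known limitations

* The transfer function is linear and time-invariant within a window;
  therapy changes or instability inside the prediction period are
  explicitly outside the model's reach.
* Coefficients are reported per window but are not uniquely
  interpretable under low excitation; compare simulated responses, not
  raw coefficients.
* The broken stick allows exactly one breakpoint; multi-phase intake
  changes within one estimation window are summarized by the best single
  turning point.
* Windows are anchored at admission; no alignment to clinical events.
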