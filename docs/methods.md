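# Methods

## Model

The velocity-storage integrator is the linear autonomous system ẋ = H x
over head-fixed (roll, pitch, yaw) slow-phase angular-velocity components,
in deg/s. The frame is right-handed with roll along the naso-occipital
axis, pitch along the interaural axis and yaw along the head vertical;
component order is (roll, pitch, yaw) everywhere in the package.

**H** is constrained to the structure

```
⎛ h_rr   0    h_yr ⎞        h_aa = −1/τ_a  (decay rates, 1/s)
⎜  0    h_pp  h_yp ⎟
⎝  0     0    h_yy ⎠
```

i.e. diagonal decay plus yaw-column couplings only. All other off-diagonal
entries are structurally zero; the package does not model more general
coupling patterns. Because H is upper triangular, its eigenvalues are the
diagonal entries and its eigenbasis has the closed form used throughout:
u_roll = (1,0,0), u_pitch = (0,1,0),
u_yaw = (h_yr/(h_yy−h_rr), h_yp/(h_yy−h_pp), 1).

Assumptions inherited from this structure:

- H is fixed: no dependence of its parameters on static head orientation
  relative to gravity (animal data suggest such dependence; out of scope).
- The yaw output gain k acts purely at the output stage, as the
  premultiplication diag(1, 1, k); the internal dynamics are unaffected.
  An alternative placement of the gain at the sensory input is not
  modelled.
- Only slow-phase velocity envelopes are represented; there is no
  fast-phase (saccadic) generation and no stimulus-delivery modelling.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| τ_roll, τ_pitch | s | 5, 5 | fast-axis decay time constants, near primary-afferent values |
| τ_yaw | s | 18 | yaw decay time constant; canonically the longest |
| h_yr, h_yp | 1/s | 0 | yaw→roll and yaw→pitch couplings; sign encodes pull direction |
| k | — | 1 | yaw output gain, restricted to (0, 1] (attenuation only) |
| x_yaw(0) | deg/s | 20 | initial yaw velocity of an idealized post-yaw-stimulation OKAN |

The 5/5/18 s defaults are the canonical illustration values for a human
upright subject. The sign convention, fixed once and used consistently:
positive h_yr tilts the subjective up toward +roll (backward-pull
polarity); negative h_yr gives a forward pull; h_yp likewise encodes
laterally directed pulls. Angles are degrees at every public interface and
radians internally.

`coupling_from_tilt` inverts the direction-cosine relation in one plane:
h = tan(γ)·(h_yy − h_aa). For τ = (5, 5, 18) s and γ = 15° this gives
h_yr = 0.0387 /s. Published tabulations of this example print 0.0378, but
that value is inconsistent with the designed 15° baseline and with the
downstream 18.4°/18.5° worked results, all of which follow from 0.0387;
the package therefore derives the coupling from the direction-cosine
relation rather than hard-coding the printed entry.

The percent "increase in pull sensation" is computed on the tangent
scale, 100·(tan γ_after / tan γ_before − 1): the tangent of γ is the
off-vertical/vertical component ratio of the subjective up, which makes a
pure gain change exactly 100·(1/k − 1) regardless of baseline — matching
the worked 24%/25% figures, which plain angle ratios (22.4%/23.3%) do not.
The angle-scale variant is exposed as `tilt_increase_pct_angle` for
comparison.

## Zero-input response and derived quantities

The closed form is evaluated term by term (see `velstore.response`); the
cross-coupled term of each fast axis rises from zero, peaks at
t = ln(h_aa/h_yy)/(h_yy − h_aa) and decays, and the state direction
converges to the gain-scaled u_yaw. At coincident rates
(|h_yy − h_aa| < 1e−9 1/s) the closed form is singular and the analytic
limit x_yaw(0)·h_ya·t·e^{ht} is substituted, keeping the response
continuous in the parameters; the peak-time formula likewise returns its
limit −1/h_yy. The same 1e−9 tolerance governs eigen-geometry: coincident
rates *with* a nonzero coupling raise `DegenerateEigenstructureError`
rather than silently producing enormous eigenvector components.

The numerical oracle is fixed-step classical RK4. For a constant linear
system the four stages collapse exactly to one multiplication by the
degree-4 Taylor polynomial of exp(dt·H); the oracle precomputes that step
matrix and applies it recursively — bit-identical to the stage-by-stage
update, but fast enough to cross-check hundreds of models per test run.
At dt = 5 ms the observed closed-form/RK4 discrepancy is below 1e−10
deg/s across the tested parameter ranges, comfortably inside the 1e−8
tolerance the suite asserts. The test suite additionally cross-checks
against `scipy.integrate.solve_ivp` so the closed form and the in-house
oracle are never the only two routes.

## Synthetic traces

`velstore.synth` emulates figure-style sampled OKAN records: the closed
form sampled at 4 Hz (the convention of published trace figures) with
i.i.d. zero-mean Gaussian noise injected per component per sample. The
published figures inject noise only for visualization and state no
distribution, so i.i.d. Gaussian with user-chosen SD is the simplest
defensible choice; the fitting tests use SD = 0.5 deg/s over 120 s as a
plausibly noisy recording. All randomness takes an explicit integer seed;
there is no global random state.

What the generator does **not** emulate: fast phases and their removal
artifacts, blinks and dropouts, drift, non-stationary noise, and any
gain/calibration error of a real recording system. Passing fit tests on
these traces therefore demonstrate correctness of the estimator under the
model's own assumptions, not performance on clinical recordings.

## Fitting

`fit_model` minimizes the sum of squared residuals between a sampled
trace and the closed-form response, via `scipy.optimize.least_squares`
(trust-region reflective, ftol 1e−10, at most 500 evaluations, with a
5-start jittered fallback on non-convergence). Time constants are
optimized as logarithms so positivity is structural. Defaults fix k = 1
and the canonical x_roll(0) = x_pitch(0) = 0 initial state.

Identifiability: in the yaw component k and x_yaw(0) appear only as the
product k·x_yaw(0), so the fitter refuses to free both simultaneously.
Roll and pitch time constants are carried into a post-yaw-stimulation
trace only through their cross-coupled terms; with a near-zero coupling
the corresponding τ is essentially unidentified. Rather than guessing,
the fitter reports per-free-parameter standard errors from the
Gauss–Newton curvature (J′J) at the optimum (delta method for the
log-scale parameters); an unidentified parameter shows up as an enormous
standard error, which the suite asserts explicitly.

## Problem sizes and numerical choices

Property tests draw random models with τ_roll, τ_pitch ∈ [2, 10] s,
τ_yaw ∈ [max+1, 30] s, couplings up to ±0.3 /s and gains in [0.5, 1] —
a generous cover of the physiologically cited ranges. The RK4
cross-check uses 200 models at dt = 5 ms over ten yaw time constants;
the noisy-recovery study uses 40 seeds at 0.5 deg/s (a once-run larger
study gave a median τ_yaw error well below the 10% bound the test
freezes); the eigen-equation property uses 1,000 models at residual
1e−10. These sizes keep the full suite in the tens of seconds while
leaving wide margins to every asserted tolerance.

## Known limitations

- The misalignment angle γ is a geometric proxy; no mapping from γ to
  symptom severity or perception is modelled.
- Combined interventions are supported only as sequential applications;
  no claims are made about combination therapy.
- The coupling-reduction ("optokinetic remedy") intervention is modelled
  purely as multiplicative scaling of h_yr/h_yp, leaving time constants
  untouched — a target value for the reduction is not specified anywhere,
  so the factor is a free parameter.
- Simultaneously nonzero h_yr and h_yp (oblique pulls) are supported by
  every formula but exercised only by generic property tests, not against
  any published worked value.
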