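# velstore

A simulator and scenario engine for the three-dimensional orientation
properties of the central vestibular **velocity-storage** mechanism, aimed
at researchers and clinicians modelling mal de débarquement syndrome
(MdDS) and related disorders of spatial orientation.

## The model

Velocity storage is modelled as a linear dynamical system

```
ẋ = H x,      x = (x_roll, x_pitch, x_yaw)ᵀ  [deg/s]
```

over head-fixed angular-velocity components. For normal upright, **H** is
diagonal with entries −1/τ_roll, −1/τ_pitch, −1/τ_yaw, so its eigenvectors
align with the head axes and the yaw eigenvector **u**_yaw — the internal
estimate of "up" — coincides with the head vertical. A gravitational-pull
state adds yaw-column cross-couplings h_yr (yaw→roll) and h_yp (yaw→pitch),
tilting the yaw eigenvector:

```
u_yaw = ( h_yr/(h_yy−h_rr),  h_yp/(h_yy−h_pp),  1 )
```

With a yaw output gain k ∈ (0, 1] (a habituation-style attenuation applied
at the output stage), the misalignment between the subjective up and the
head vertical is

```
cos γ = k / √( (h_yr/(h_yy−h_rr))² + (h_yp/(h_yy−h_pp))² + k² )
```

γ is the model's proxy for the perceived pull. The central result the
package operationalizes: *both* attenuation interventions — shortening
τ_yaw or lowering k — **increase** γ whenever a pull coupling is present,
so attenuation therapy can worsen a pull sensation even while helping
otherwise. The zero-input response of the system is the slow-phase
velocity profile of idealized optokinetic after-nystagmus (OKAN); its
decay trajectory approaches u_yaw, which is how the misalignment would be
read out of eye-movement data.

Layers:

- `velstore.model` — system-matrix construction, eigenbasis, misalignment
  angle, and the inverse problem (coupling from a target tilt).
- `velstore.response` — closed-form zero-input response, a fixed-step RK4
  numerical oracle, cross-coupled peak times and asymptotes.
- `velstore.scenarios` — before/after intervention pipelines.
- `velstore.synth` — figure-style sampled traces (4 Hz, seeded Gaussian
  noise).
- `velstore.fit` — least-squares recovery of model parameters from sampled
  traces (an extension beyond the published worked computations).
- `velstore.cli` — the `velstore simulate|scenario|fit` command line.

## Worked example

```python
from velstore import (TimeConstants, Intervention, build_pull,
                      coupling_from_tilt, run_scenario)

tcs = TimeConstants(tau_roll=5.0, tau_pitch=5.0, tau_yaw=18.0)
coupling = coupling_from_tilt(15.0, "roll-yaw", tcs)
baseline = build_pull(tcs, coupling)
print(f"yaw-to-roll coupling h_yr = {coupling.h_yr:.4f} /s")

for iv in (Intervention("set_yaw_time_constant", 12.0),
           Intervention("set_yaw_gain", 0.8)):
    res = run_scenario(baseline, iv)
    print(f"{iv.kind} -> {iv.value}: "
          f"gamma {res.gamma_before:.1f} -> {res.gamma_after:.1f} deg "
          f"(+{res.increase_pct:.0f}% pull sensation)")
```

prints

```
yaw-to-roll coupling h_yr = 0.0387 /s
set_yaw_time_constant -> 12.0: gamma 15.0 -> 18.4 deg (+24% pull sensation)
set_yaw_gain -> 0.8: gamma 15.0 -> 18.5 deg (+25% pull sensation)
```

Read: a patient whose subjective vertical is pitched 15° off true
(h_yr = 0.0387 /s solves the direction-cosine relation for that tilt)
would, after a yaw time-constant reduction from 18 s to 12 s, perceive an
18.4° tilt — a 24% stronger pull on the tangent scale — and after a 20%
output-gain reduction an 18.5° tilt, a 25% stronger pull. The 25% figure
for a pure gain change is exactly 100·(1/k − 1) and is independent of the
baseline tilt.

The same scenarios are shipped as CLI configs:

```
velstore scenario --config examples/scenario_yaw_tau_reduction.json --out-dir out/
```

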