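"""Velocity-storage attenuation scenarios as an executable pipeline.

Two habituation-style interventions reduce the contribution of velocity
storage: shortening the yaw time constant, or lowering the yaw output gain.
Applied to a model that already carries a gravitational-pull coupling,
both *increase* the misalignment between the head vertical and its internal
representation — the model's account of why attenuation therapy can worsen
a pull sensation.  A third intervention scales the coupling terms toward
zero, emulating the optokinetic-stimulation remedy that targets the pull
directly.

Interventions are absolute setters for the time constant and the gain
(matching how the worked examples state them: "set tau_yaw to 12 s",
"set k to 0.8"); the coupling remedy is a multiplicative factor in [0, 1]
because only a reduction, not a target value, is specified for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .model import (
    CouplingTerms,
    TimeConstants,
    VSModel,
    misalignment_angle,
    model_to_dict,
    tilt_increase_pct,
    tilt_increase_pct_angle,
)
from .response import StateVector, Trajectory, default_grid, zero_input_response

__all__ = ["Intervention", "ScenarioResult", "apply_intervention", "run_scenario"]

INTERVENTION_KINDS = ("set_yaw_time_constant", "set_yaw_gain", "scale_coupling")


@dataclass(frozen=True)
class Intervention:
    """One attenuation (or remedy) step applied to a baseline model.

    kind: 'set_yaw_time_constant' (value in seconds, > 0),
          'set_yaw_gain' (value in (0, 1]),
          'scale_coupling' (factor in [0, 1]; 0 is the full remedy).
    """

    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in INTERVENTION_KINDS:
            raise InvalidParameterError(
                f"unknown intervention kind {self.kind!r}; "
                f"expected one of {INTERVENTION_KINDS}"
            )
        v = self.value
        if not np.isfinite(v):
            raise InvalidParameterError("intervention value must be finite")
        if self.kind == "set_yaw_time_constant" and v <= 0:
            raise InvalidParameterError(
                f"yaw time constant must be positive seconds, got {v!r}"
            )
        if self.kind == "set_yaw_gain" and not (0.0 < v <= 1.0):
            raise InvalidParameterError(f"yaw gain must lie in (0, 1], got {v!r}")
        if self.kind == "scale_coupling" and not (0.0 <= v <= 1.0):
            raise InvalidParameterError(
                f"coupling scale factor must lie in [0, 1], got {v!r}"
            )


def apply_intervention(model: VSModel, iv: Intervention) -> VSModel:
    """Return the modified model; every untouched parameter is preserved."""
    if iv.kind == "set_yaw_time_constant":
        tcs = model.time_constants
        return replace(
            model,
            time_constants=TimeConstants(tcs.tau_roll, tcs.tau_pitch, iv.value),
        )
    if iv.kind == "set_yaw_gain":
        return replace(model, yaw_gain=iv.value)
    c = model.coupling
    return replace(
        model, coupling=CouplingTerms(c.h_yr * iv.value, c.h_yp * iv.value)
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Before/after summary of an intervention on a pull model.

    ``increase_pct`` is on the tangent scale (the off-vertical/vertical
    component ratio of the subjective up); ``increase_pct_angle`` is the
    plain ratio of angles.  Both are None when the baseline has no
    misalignment (the ratios are undefined there).
    """

    baseline_model: VSModel
    modified_model: VSModel
    gamma_before: float
    gamma_after: float
    increase_pct: float | None
    increase_pct_angle: float | None
    baseline_trajectory: Trajectory
    modified_trajectory: Trajectory

    def to_report_dict(self) -> dict:
        return {
            "baseline": model_to_dict(self.baseline_model),
            "modified": model_to_dict(self.modified_model),
            "gamma_before_deg": self.gamma_before,
            "gamma_after_deg": self.gamma_after,
            "increase_pct_tangent": self.increase_pct,
            "increase_pct_angle": self.increase_pct_angle,
        }


def run_scenario(
    baseline: VSModel,
    iv: Intervention,
    grid: np.ndarray | None = None,
    x0: StateVector | None = None,
) -> ScenarioResult:
    """Apply ``iv`` to ``baseline`` and report paired angles and trajectories.

    The grid defaults to 0-120 s at 4 Hz; the initial state defaults to the
    canonical post-yaw-stimulation condition (roll = pitch = 0).
    Deterministic given its inputs.
    """
    if grid is None:
        grid = default_grid()
    if x0 is None:
        x0 = StateVector()
    modified = apply_intervention(baseline, iv)
    gamma_before = misalignment_angle(baseline)
    gamma_after = misalignment_angle(modified)
    if gamma_before > 0.0:
        inc_tan = tilt_increase_pct(baseline, modified)
        inc_ang = tilt_increase_pct_angle(baseline, modified)
    else:
        inc_tan = inc_ang = None
    return ScenarioResult(
        baseline_model=baseline,
        modified_model=modified,
        gamma_before=gamma_before,
        gamma_after=gamma_after,
        increase_pct=inc_tan,
        increase_pct_angle=inc_ang,
        baseline_trajectory=zero_input_response(baseline, x0, grid),
        modified_trajectory=zero_input_response(modified, x0, grid),
    )


def write_scenario_report(
    result: ScenarioResult, iv: Intervention, out_dir: str | Path, stem: str = "scenario"
) -> dict:
    """Write the report JSON and paired trajectory CSVs; return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = result.to_report_dict()
    report["intervention"] = {"kind": iv.kind, "value": iv.value}
    (out / f"{stem}.json").write_text(json.dumps(report, indent=2) + "\n")
    result.baseline_trajectory.to_csv(out / f"{stem}_baseline.csv")
    result.modified_trajectory.to_csv(out / f"{stem}_modified.csv")
    return report
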