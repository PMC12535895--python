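"""Synthetic sampled OKAN traces.

Figure-style traces: the closed-form zero-input response sampled at a
fixed rate (default four samples per second) with independent zero-mean
Gaussian noise injected per component per sample.  The noise emulates the
visual jitter of published scatter traces and, for the fitting module,
measurement noise on slow-phase velocity estimates; its standard deviation
is a user parameter (deg/s).  All randomness is driven by an explicit
integer seed — there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .model import VSModel, model_to_dict
from .response import StateVector, Trajectory, default_grid, zero_input_response

__all__ = ["SampledTrace", "generate_trace", "write_trace_bundle", "read_trace_bundle"]

DEFAULT_SAMPLE_RATE = 4.0  # samples per second


@dataclass(frozen=True)
class SampledTrace:
    """A noisy sampled trajectory plus its generation metadata."""

    trace: Trajectory
    noise_sd: float
    seed: int
    sample_rate: float = DEFAULT_SAMPLE_RATE


def generate_trace(
    model: VSModel,
    x0: StateVector,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> SampledTrace:
    """Sample the closed-form response and inject i.i.d. Gaussian noise.

    Deterministic given ``seed``; with ``noise_sd = 0`` the samples equal
    the closed-form response exactly.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    if noise_sd < 0 or not np.isfinite(noise_sd):
        raise InvalidParameterError("noise_sd must be finite and >= 0")
    grid = default_grid(duration_s, sample_rate)
    clean = zero_input_response(model, x0, grid)
    states = clean.states
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        states = states + rng.normal(0.0, noise_sd, size=states.shape)
    noisy = Trajectory(grid, states, gain_applied=True)
    return SampledTrace(noisy, noise_sd, seed, sample_rate)


def write_trace_bundle(
    sampled: SampledTrace,
    model: VSModel,
    x0: StateVector,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> Path:
    """Write the trace CSV plus a ground-truth sidecar JSON.

    The sidecar records the generating model, initial state, noise level
    and seed — the bundle the fitting tests consume.
    """
    csv_path = Path(csv_path)
    sampled.trace.to_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    sidecar = {
        "model": model_to_dict(model),
        "x0_dps": {"roll": x0.x_roll, "pitch": x0.x_pitch, "yaw": x0.x_yaw},
        "noise_sd_dps": sampled.noise_sd,
        "seed": sampled.seed,
        "sample_rate_hz": sampled.sample_rate,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return Path(sidecar_path)


def read_trace_bundle(csv_path: str | Path) -> tuple[Trajectory, dict]:
    """Read a trace CSV and its sidecar JSON (ground truth) back in."""
    csv_path = Path(csv_path)
    traj = Trajectory.from_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return traj, sidecar
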