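"""Zero-input (idealized OKAN) response of the velocity-storage system.

With no further input the system x' = H x decays from its initial state.
Because H is upper triangular with yaw-column couplings only, the response
has the closed form (per component, with h_aa the roll or pitch rate and
h_ya the corresponding coupling):

    x_a(t)   = x_a(0) e^{h_aa t} + x_yaw(0) (h_ya/(h_yy-h_aa)) (e^{h_yy t} - e^{h_aa t})
    x_yaw(t) = k x_yaw(0) e^{h_yy t}

The cross-coupled term starts at zero, peaks at t = ln(h_aa/h_yy)/(h_yy-h_aa)
and then decays; as t -> infinity the state direction approaches the
(gain-scaled) yaw eigenvector, which is why the tail of OKAN carries the
misalignment information.  The output gain k scales only the reported yaw
component; the internal dynamics are unchanged.

When the two decay rates coincide the closed form is replaced by its
analytic limit x_yaw(0) h_ya t e^{h t}, keeping the response continuous in
the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .model import (
    DEGENERACY_TOL,
    OrientationVector,
    VSModel,
    misalignment_angle,
    subjective_up,
)

__all__ = [
    "StateVector",
    "Trajectory",
    "default_grid",
    "zero_input_response",
    "numeric_response_oracle",
    "cross_coupled_peak_time",
    "asymptote_direction",
]

#: Canonical initial yaw velocity (deg/s) used by fixtures and examples;
#: an idealized OKAN after yaw optokinetic stimulation starts with zero
#: roll and pitch velocity and some nonzero yaw velocity.
DEFAULT_X_YAW_0 = 20.0

CSV_COLUMNS = ("time_s", "roll_dps", "pitch_dps", "yaw_dps")


@dataclass(frozen=True)
class StateVector:
    """Angular velocities (deg/s) about the head roll, pitch and yaw axes."""

    x_roll: float = 0.0
    x_pitch: float = 0.0
    x_yaw: float = DEFAULT_X_YAW_0

    def __post_init__(self) -> None:
        for name in ("x_roll", "x_pitch", "x_yaw"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_roll, self.x_pitch, self.x_yaw])


@dataclass(frozen=True)
class Trajectory:
    """Sampled (roll, pitch, yaw) velocity time series.

    ``states`` has shape (n, 3) in component order (roll, pitch, yaw);
    ``gain_applied`` records whether yaw values are k-scaled output values.
    """

    times: np.ndarray
    states: np.ndarray
    gain_applied: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or times.size == 0:
            raise InvalidParameterError("times must be a non-empty 1-D array")
        if np.any(np.diff(times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if states.shape != (times.size, 3):
            raise InvalidParameterError(
                f"states must have shape ({times.size}, 3), got {states.shape}"
            )

    @property
    def roll(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def pitch(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def yaw(self) -> np.ndarray:
        return self.states[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "roll_dps": self.roll,
                "pitch_dps": self.pitch,
                "yaw_dps": self.yaw,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, gain_applied: bool = True) -> "Trajectory":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidParameterError(
                f"trajectory CSV is missing columns {missing}; "
                f"expected header {list(CSV_COLUMNS)}"
            )
        return cls(
            times=df["time_s"].to_numpy(),
            states=df[["roll_dps", "pitch_dps", "yaw_dps"]].to_numpy(),
            gain_applied=gain_applied,
        )


def default_grid(duration_s: float = 120.0, rate_hz: float = 4.0) -> np.ndarray:
    """Uniform sample grid from 0 to duration inclusive (default 4 Hz)."""
    if duration_s <= 0 or rate_hz <= 0:
        raise InvalidParameterError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    return np.arange(n + 1) / rate_hz


def _cross_term(
    h_ya: float, h_aa: float, h_yy: float, t: np.ndarray
) -> np.ndarray:
    """x_yaw(0)-normalized cross-coupled term, with the equal-rate limit."""
    if h_ya == 0.0:
        return np.zeros_like(t)
    if abs(h_yy - h_aa) < DEGENERACY_TOL:
        return h_ya * t * np.exp(h_yy * t)
    return (h_ya / (h_yy - h_aa)) * (np.exp(h_yy * t) - np.exp(h_aa * t))


def zero_input_response(
    model: VSModel, x0: StateVector, times: np.ndarray
) -> Trajectory:
    """Closed-form response to initial state ``x0`` on the given grid.

    Times must be non-empty, non-negative and strictly increasing.  The yaw
    output gain is applied to the yaw component only (``gain_applied=True``).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidParameterError("times must be a non-empty 1-D sequence")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError(
            "times must be non-negative and strictly increasing"
        )
    tcs, c, k = model.time_constants, model.coupling, model.yaw_gain
    roll = x0.x_roll * np.exp(tcs.h_rr * t) + x0.x_yaw * _cross_term(
        c.h_yr, tcs.h_rr, tcs.h_yy, t
    )
    pitch = x0.x_pitch * np.exp(tcs.h_pp * t) + x0.x_yaw * _cross_term(
        c.h_yp, tcs.h_pp, tcs.h_yy, t
    )
    yaw = k * x0.x_yaw * np.exp(tcs.h_yy * t)
    return Trajectory(t, np.column_stack([roll, pitch, yaw]), gain_applied=True)


def numeric_response_oracle(
    model: VSModel, x0: StateVector, t_end: float, dt: float
) -> Trajectory:
    """Fixed-step 4th-order Runge-Kutta integration of x' = H x.

    An independent numerical check of the closed form, used in tests and
    cross-validation; the yaw output gain is applied after integration.

    Because the system is linear and autonomous, the four classical RK4
    stages collapse exactly to one multiplication by the degree-4 Taylor
    polynomial of exp(dt H); the step matrix is precomputed and applied
    recursively, which is bit-identical to the stage-by-stage update but
    much cheaper.
    """
    if dt <= 0 or t_end <= 0:
        raise InvalidParameterError("dt and t_end must be positive")
    A = model.matrix * dt
    # RK4 step matrix: I + A + A^2/2 + A^3/6 + A^4/24
    step = np.eye(3) + A @ (np.eye(3) + A @ (np.eye(3) + A @ (np.eye(3) + A / 4.0) / 3.0) / 2.0)
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 3))
    x = x0.as_array().astype(float)
    states[0] = x
    for i in range(n):
        x = step @ x
        states[i + 1] = x
    states[:, 2] *= model.yaw_gain
    return Trajectory(times, states, gain_applied=True)


def cross_coupled_peak_time(model: VSModel, plane: str) -> float:
    """Time (s) at which the cross-coupled term of the response peaks.

    Analytic form ln(h_aa/h_yy)/(h_yy - h_aa) for the chosen plane; in the
    equal-rate limit the peak time tends to the common time constant
    -1/h_yy, which is returned instead of raising.
    """
    if plane not in ("roll-yaw", "pitch-yaw"):
        raise InvalidParameterError(
            f"plane must be 'roll-yaw' or 'pitch-yaw', got {plane!r}"
        )
    tcs = model.time_constants
    h_aa = tcs.h_rr if plane == "roll-yaw" else tcs.h_pp
    h_yy = tcs.h_yy
    if abs(h_yy - h_aa) < DEGENERACY_TOL:
        return -1.0 / h_yy
    return float(np.log(h_aa / h_yy) / (h_yy - h_aa))


def asymptote_direction(model: VSModel) -> OrientationVector:
    """Direction the decaying state approaches for large t.

    The state direction converges to the gain-scaled yaw eigenvector (the
    subjective up) whenever x_yaw(0) != 0, so this simply returns
    :func:`velstore.model.subjective_up`; the dynamic convergence is
    verified in the test suite.
    """
    return subjective_up(model)


def trajectory_angle_to(traj_state: np.ndarray, direction: OrientationVector) -> float:
    """Angle (degrees) between a state vector and a reference direction."""
    u = direction.as_array()
    x = np.asarray(traj_state, dtype=float)
    c = float(x @ u / (np.linalg.norm(x) * np.linalg.norm(u)))
    return float(np.degrees(np.arccos(np.clip(abs(c), -1.0, 1.0))))
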