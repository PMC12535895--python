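"""Structure and eigen-geometry of the velocity-storage system matrix.

The velocity-storage integrator is modelled as a linear dynamical system
x' = H x over head-fixed (roll, pitch, yaw) angular-velocity components.
In the normal upright condition H is diagonal with entries -1/tau for the
roll, pitch and yaw decay time constants, so its eigenvectors align with
the head axes and the yaw eigenvector is the internal estimate of "up".

A gravitational-pull state is expressed by yaw-column off-diagonal
couplings h_yr (yaw-to-roll) and h_yp (yaw-to-pitch).  The yaw eigenvector
then becomes

    u_yaw = (h_yr/(h_yy - h_rr), h_yp/(h_yy - h_pp), 1),

which no longer aligns with the head vertical; the angle gamma between the
(optionally output-gain-scaled) u_yaw and the head vertical is the model's
proxy for the perceived pull.  A yaw output gain k in (0, 1] contracts only
the yaw component of the output, giving v_yaw = diag(1, 1, k) u_yaw and

    cos(gamma) = k / sqrt((h_yr/(h_yy-h_rr))^2 + (h_yp/(h_yy-h_pp))^2 + k^2).

Angles are degrees at every public interface and radians internally.
Component order everywhere is (roll, pitch, yaw); the frame is the
right-handed head-fixed frame (roll = naso-occipital, pitch = interaural,
yaw = head-vertical axis).  Positive h_yr tilts the subjective up toward
+roll (a backward-pull polarity); negative h_yr gives the forward pull, and
h_yp likewise encodes laterally directed pulls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateEigenstructureError,
    InvalidParameterError,
    UndefinedRatioError,
)

__all__ = [
    "DEGENERACY_TOL",
    "TimeConstants",
    "CouplingTerms",
    "OrientationVector",
    "VSModel",
    "build_normal",
    "build_pull",
    "subjective_up",
    "eigenbasis",
    "misalignment_angle",
    "coupling_from_tilt",
    "tilt_increase_pct",
    "tilt_increase_pct_angle",
    "model_to_dict",
    "model_from_dict",
]

#: Two decay rates closer than this (1/s) with a nonzero coupling between
#: them are treated as coincident: the closed-form eigenvector is singular.
DEGENERACY_TOL = 1e-9


def _require_finite_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise InvalidParameterError(
            f"{name} must be a finite positive number, got {value!r}"
        )


@dataclass(frozen=True)
class TimeConstants:
    """Decay time constants (seconds) of the roll, pitch and yaw components.

    Each tau relates to the system-matrix diagonal by h = -1/tau.  The
    physiologically typical regime has the yaw time constant longest;
    :meth:`is_canonical` tests for it without forbidding other regimes.
    """

    tau_roll: float
    tau_pitch: float
    tau_yaw: float

    def __post_init__(self) -> None:
        _require_finite_positive("tau_roll", self.tau_roll)
        _require_finite_positive("tau_pitch", self.tau_pitch)
        _require_finite_positive("tau_yaw", self.tau_yaw)

    @property
    def h_rr(self) -> float:
        return -1.0 / self.tau_roll

    @property
    def h_pp(self) -> float:
        return -1.0 / self.tau_pitch

    @property
    def h_yy(self) -> float:
        return -1.0 / self.tau_yaw

    def is_canonical(self) -> bool:
        """True when yaw decays slowest (tau_yaw > tau_roll and tau_pitch)."""
        return self.tau_yaw > self.tau_roll and self.tau_yaw > self.tau_pitch


@dataclass(frozen=True)
class CouplingTerms:
    """Yaw-column cross-couplings (1/s): h_yr yaw-to-roll, h_yp yaw-to-pitch.

    Sign encodes pull polarity; zero means no pull in that plane.
    """

    h_yr: float = 0.0
    h_yp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("h_yr", "h_yp"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")

    def is_zero(self) -> bool:
        return self.h_yr == 0.0 and self.h_yp == 0.0


@dataclass(frozen=True)
class OrientationVector:
    """A direction in the head-fixed frame (dimensionless components)."""

    roll_component: float
    pitch_component: float
    yaw_component: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.roll_component, self.pitch_component, self.yaw_component]
        )


@dataclass(frozen=True)
class VSModel:
    """A velocity-storage model: time constants, couplings, yaw output gain.

    The implied 3x3 system matrix has diagonal (-1/tau_roll, -1/tau_pitch,
    -1/tau_yaw) and the only permitted off-diagonal nonzeros are h_yr at
    (roll-row, yaw-column) and h_yp at (pitch-row, yaw-column).  The gain k
    acts at the output stage only (it scales the reported yaw component,
    never the internal dynamics); k = 1 is the identity case and k > 1 is
    rejected as outside the habituation framing.
    """

    time_constants: TimeConstants
    coupling: CouplingTerms
    yaw_gain: float = 1.0

    def __post_init__(self) -> None:
        k = self.yaw_gain
        if not (math.isfinite(k) and 0.0 < k <= 1.0):
            raise InvalidParameterError(
                f"yaw_gain must lie in (0, 1], got {k!r}"
            )

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 system matrix H (1/s), rows/cols in (roll, pitch, yaw)."""
        tcs, c = self.time_constants, self.coupling
        return np.array(
            [
                [tcs.h_rr, 0.0, c.h_yr],
                [0.0, tcs.h_pp, c.h_yp],
                [0.0, 0.0, tcs.h_yy],
            ]
        )

    def roll_plane_degenerate(self) -> bool:
        tcs = self.time_constants
        return (
            abs(tcs.h_yy - tcs.h_rr) < DEGENERACY_TOL
            and self.coupling.h_yr != 0.0
        )

    def pitch_plane_degenerate(self) -> bool:
        tcs = self.time_constants
        return (
            abs(tcs.h_yy - tcs.h_pp) < DEGENERACY_TOL
            and self.coupling.h_yp != 0.0
        )

    def is_degenerate(self) -> bool:
        """True when a closed-form eigenvector component divides by ~0."""
        return self.roll_plane_degenerate() or self.pitch_plane_degenerate()


def build_normal(tcs: TimeConstants) -> VSModel:
    """Model for the normal upright condition: diagonal H, unit gain."""
    return VSModel(tcs, CouplingTerms(0.0, 0.0), 1.0)


def build_pull(tcs: TimeConstants, coupling: CouplingTerms) -> VSModel:
    """Model for a gravitational-pull state: yaw-column couplings, unit gain."""
    return VSModel(tcs, coupling, 1.0)


def _check_nondegenerate(model: VSModel) -> None:
    if model.is_degenerate():
        tcs = model.time_constants
        raise DegenerateEigenstructureError(
            "coincident decay rates with nonzero coupling "
            f"(h_rr={tcs.h_rr:.6g}, h_pp={tcs.h_pp:.6g}, h_yy={tcs.h_yy:.6g}); "
            "the closed-form yaw eigenvector is singular"
        )


def _raw_ratios(model: VSModel) -> tuple[float, float]:
    """The roll and pitch components of u_yaw (gain not applied)."""
    _check_nondegenerate(model)
    tcs, c = model.time_constants, model.coupling
    r = c.h_yr / (tcs.h_yy - tcs.h_rr) if c.h_yr != 0.0 else 0.0
    p = c.h_yp / (tcs.h_yy - tcs.h_pp) if c.h_yp != 0.0 else 0.0
    return r, p


def subjective_up(model: VSModel) -> OrientationVector:
    """The internal estimate of "up": the gain-scaled yaw eigenvector.

    Returns (h_yr/(h_yy-h_rr), h_yp/(h_yy-h_pp), k).  For a diagonal model
    this is (0, 0, k), i.e. aligned with the head vertical.
    """
    r, p = _raw_ratios(model)
    return OrientationVector(r, p, model.yaw_gain)


def eigenbasis(
    model: VSModel,
) -> tuple[OrientationVector, OrientationVector, OrientationVector]:
    """Closed-form eigenvectors (u_roll, u_pitch, u_yaw) of H.

    u_roll and u_pitch always align with the head roll and pitch axes; the
    output gain is NOT applied here (it is a property of the output stage,
    not of H).  Eigenvalues are h_rr, h_pp, h_yy respectively.
    """
    r, p = _raw_ratios(model)
    return (
        OrientationVector(1.0, 0.0, 0.0),
        OrientationVector(0.0, 1.0, 0.0),
        OrientationVector(r, p, 1.0),
    )


def misalignment_angle(model: VSModel) -> float:
    """Angle gamma (degrees) between subjective up and the head vertical.

    Equals arccos(k / sqrt(r^2 + p^2 + k^2)) with r, p the u_yaw roll and
    pitch components; implemented as atan2(hypot(r, p), k) for accuracy at
    small angles.  Always in [0, 90).
    """
    r, p = _raw_ratios(model)
    return math.degrees(math.atan2(math.hypot(r, p), model.yaw_gain))


def coupling_from_tilt(
    tilt_deg: float, plane: str, tcs: TimeConstants
) -> CouplingTerms:
    """Solve for the single coupling giving a target misalignment.

    Inverts the direction-cosine relation at unit gain in the chosen plane
    ("roll-yaw" -> h_yr, "pitch-yaw" -> h_yp): h = tan(tilt) * (h_yy - h_aa).
    In the canonical regime (yaw slowest) h_yy - h_aa > 0, so a positive
    tilt yields a positive coupling (backward-pull polarity for roll-yaw).
    """
    if not (0.0 <= tilt_deg < 90.0):
        raise InvalidParameterError(
            f"tilt must lie in [0, 90) degrees, got {tilt_deg!r}"
        )
    if plane not in ("roll-yaw", "pitch-yaw"):
        raise InvalidParameterError(
            f"plane must be 'roll-yaw' or 'pitch-yaw', got {plane!r}"
        )
    if tilt_deg == 0.0:
        return CouplingTerms(0.0, 0.0)
    h_aa = tcs.h_rr if plane == "roll-yaw" else tcs.h_pp
    gap = tcs.h_yy - h_aa
    if abs(gap) < DEGENERACY_TOL:
        raise DegenerateEigenstructureError(
            f"decay rates coincide in the {plane} plane; "
            "no coupling can produce a finite eigenvector tilt"
        )
    h = math.tan(math.radians(tilt_deg)) * gap
    if plane == "roll-yaw":
        return CouplingTerms(h_yr=h, h_yp=0.0)
    return CouplingTerms(h_yr=0.0, h_yp=h)


def _tan_gamma(model: VSModel) -> float:
    r, p = _raw_ratios(model)
    return math.hypot(r, p) / model.yaw_gain


def tilt_increase_pct(before: VSModel, after: VSModel) -> float:
    """Percent change of the pull sensation on the tangent scale.

    Returns 100 * (tan(gamma_after) / tan(gamma_before) - 1).  The tangent
    of gamma is the off-vertical/vertical component ratio of the subjective
    up, so for a pure gain change k the result is exactly 100 * (1/k - 1),
    independent of the baseline tilt.
    """
    t_before = _tan_gamma(before)
    if t_before == 0.0:
        raise UndefinedRatioError(
            "baseline misalignment is zero; the percent increase is undefined"
        )
    return 100.0 * (_tan_gamma(after) / t_before - 1.0)


def tilt_increase_pct_angle(before: VSModel, after: VSModel) -> float:
    """Percent change of the misalignment angle itself (alternative metric).

    100 * (gamma_after / gamma_before - 1) on the angles in degrees.  Unlike
    the tangent-scale metric this is not baseline-independent for gain
    changes; it is provided for comparison only.
    """
    g_before = misalignment_angle(before)
    if g_before == 0.0:
        raise UndefinedRatioError(
            "baseline misalignment is zero; the percent increase is undefined"
        )
    return 100.0 * (misalignment_angle(after) / g_before - 1.0)


# --- serialization ----------------------------------------------------------

_MODEL_KEYS = (
    "tau_roll_s",
    "tau_pitch_s",
    "tau_yaw_s",
    "h_yr_per_s",
    "h_yp_per_s",
    "yaw_gain",
)


def model_to_dict(model: VSModel) -> dict:
    """Flat JSON-ready mapping of the model parameters."""
    tcs, c = model.time_constants, model.coupling
    return {
        "tau_roll_s": tcs.tau_roll,
        "tau_pitch_s": tcs.tau_pitch,
        "tau_yaw_s": tcs.tau_yaw,
        "h_yr_per_s": c.h_yr,
        "h_yp_per_s": c.h_yp,
        "yaw_gain": model.yaw_gain,
    }


def model_from_dict(d: dict) -> VSModel:
    """Inverse of :func:`model_to_dict`; unknown keys are rejected."""
    unknown = set(d) - set(_MODEL_KEYS)
    if unknown:
        raise InvalidParameterError(
            f"unknown model keys: {sorted(unknown)}; expected {_MODEL_KEYS}"
        )
    missing = set(_MODEL_KEYS) - set(d)
    if missing:
        raise InvalidParameterError(f"missing model keys: {sorted(missing)}")
    return VSModel(
        TimeConstants(d["tau_roll_s"], d["tau_pitch_s"], d["tau_yaw_s"]),
        CouplingTerms(d["h_yr_per_s"], d["h_yp_per_s"]),
        d["yaw_gain"],
    )


def with_yaw_gain(model: VSModel, k: float) -> VSModel:
    """A copy of the model with the output gain replaced."""
    return replace(model, yaw_gain=k)
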