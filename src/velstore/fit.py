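"""Parameter recovery from sampled slow-phase velocity traces.

This module is an extension beyond the published worked examples: it
answers the practical question of estimating velocity-storage parameters
from recorded OKAN traces.  The forward model is the closed-form zero-input
response (see :mod:`velstore.response`); fitting minimizes the sum of
squared residuals between the sampled trace and that closed form over the
free parameters, using trust-region nonlinear least squares
(:func:`scipy.optimize.least_squares`).

Parameterization: time constants are optimized in log space (positivity is
then structural rather than a constraint); couplings, gain and initial
state are raw.  A single post-yaw-stimulation trace carries the yaw output
gain k and the initial yaw velocity x_yaw(0) only through their product
k * x_yaw(0), so the two are not jointly identifiable: the fitter refuses
to free both at once and by default holds k = 1.

Uncertainty: per-parameter standard errors from the Gauss-Newton curvature
(J'J) at the optimum, with the delta method applied to log-scale
parameters.  These are local, noise-level-dependent quantities — roll and
pitch time constants are only weakly identified when the corresponding
coupling is near zero, and their standard errors say so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitInputError
from .model import CouplingTerms, TimeConstants, VSModel
from .response import StateVector, Trajectory, zero_input_response
from .synth import SampledTrace

__all__ = ["FitResult", "fit_model", "PARAM_NAMES", "DEFAULT_FIXED"]

PARAM_NAMES = (
    "tau_roll",
    "tau_pitch",
    "tau_yaw",
    "h_yr",
    "h_yp",
    "yaw_gain",
    "x_roll",
    "x_pitch",
    "x_yaw",
)

#: Default fixed set: unit output gain and the canonical post-yaw-OKS
#: initial condition (zero roll and pitch velocity).
DEFAULT_FIXED = {"yaw_gain": 1.0, "x_roll": 0.0, "x_pitch": 0.0}

_LOG_PARAMS = {"tau_roll", "tau_pitch", "tau_yaw"}

DEFAULT_BOUNDS = {
    "tau_roll": (0.1, 300.0),
    "tau_pitch": (0.1, 300.0),
    "tau_yaw": (0.1, 300.0),
    "h_yr": (-5.0, 5.0),
    "h_yp": (-5.0, 5.0),
    "yaw_gain": (1e-3, 1.0),
    "x_roll": (-500.0, 500.0),
    "x_pitch": (-500.0, 500.0),
    "x_yaw": (-500.0, 500.0),
}

MAX_NFEV = 500
FTOL = 1e-10
N_MULTISTART = 5


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit.

    ``param_stderr`` maps each *free* parameter name to its curvature-based
    standard error (NaN where the curvature is singular).
    """

    estimate: VSModel
    initial_state_estimate: StateVector
    residual_rms: float
    converged: bool
    n_iterations: int
    param_stderr: dict[str, float]
    cost: float


def _as_trajectory(trace: SampledTrace | Trajectory) -> Trajectory:
    if isinstance(trace, SampledTrace):
        return trace.trace
    return trace


def _params_to_model(p: dict[str, float]) -> tuple[VSModel, StateVector]:
    model = VSModel(
        TimeConstants(p["tau_roll"], p["tau_pitch"], p["tau_yaw"]),
        CouplingTerms(p["h_yr"], p["h_yp"]),
        p["yaw_gain"],
    )
    x0 = StateVector(p["x_roll"], p["x_pitch"], p["x_yaw"])
    return model, x0


def _default_init(traj: Trajectory, fixed: dict[str, float]) -> dict[str, float]:
    init = {
        "tau_roll": 5.0,
        "tau_pitch": 5.0,
        "tau_yaw": 18.0,
        "h_yr": 0.0,
        "h_yp": 0.0,
        "yaw_gain": 1.0,
        "x_roll": 0.0,
        "x_pitch": 0.0,
        # first yaw sample approximates k * x_yaw(0); divide by the gain
        # if the caller fixed one
        "x_yaw": float(traj.yaw[0]) / fixed.get("yaw_gain", 1.0),
    }
    init.update(fixed)
    return init


def fit_model(
    trace: SampledTrace | Trajectory,
    fixed: dict[str, float] | None = None,
    init: VSModel | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Fit the closed-form response to a sampled trace by least squares.

    Parameters
    ----------
    trace
        A :class:`~velstore.synth.SampledTrace` or plain
        :class:`~velstore.response.Trajectory` with at least 10 samples.
    fixed
        Mapping of parameter name (see ``PARAM_NAMES``) to a held value.
        When omitted, ``DEFAULT_FIXED`` applies (k = 1, zero initial roll
        and pitch velocity).  At least one of ``yaw_gain`` and ``x_yaw``
        must be fixed — they enter the yaw trace only as a product.
    init
        Optional model whose parameters seed the optimizer (its couplings,
        time constants and gain); defaults to time constants (5, 5, 18) s
        with zero coupling.
    bounds
        Per-parameter (low, high) boxes overriding ``DEFAULT_BOUNDS``.

    Non-convergence is flagged in the result, not raised; a multi-start
    fallback (5 jittered initializations) runs first when the initial
    attempt fails to converge.  Deterministic given data, ``fixed`` and
    ``init``.
    """
    traj = _as_trajectory(trace)
    if traj.times.size < 10:
        raise FitInputError(
            f"need at least 10 samples to fit, got {traj.times.size}"
        )
    fixed = dict(DEFAULT_FIXED if fixed is None else fixed)
    unknown = set(fixed) - set(PARAM_NAMES)
    if unknown:
        raise FitInputError(f"unknown fixed parameters: {sorted(unknown)}")
    if "yaw_gain" not in fixed and "x_yaw" not in fixed:
        raise FitInputError(
            "yaw_gain and x_yaw enter the yaw trace only as the product "
            "k * x_yaw(0) and cannot both be free; fix one of them"
        )
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)

    init_params = _default_init(traj, fixed)
    if init is not None:
        tcs, c = init.time_constants, init.coupling
        init_params.update(
            tau_roll=tcs.tau_roll,
            tau_pitch=tcs.tau_pitch,
            tau_yaw=tcs.tau_yaw,
            h_yr=c.h_yr,
            h_yp=c.h_yp,
            yaw_gain=init.yaw_gain,
        )
        init_params.update(fixed)

    free_names = [n for n in PARAM_NAMES if n not in fixed]

    def pack(p: dict[str, float]) -> np.ndarray:
        return np.array(
            [
                math.log(p[n]) if n in _LOG_PARAMS else p[n]
                for n in free_names
            ]
        )

    def unpack(theta: np.ndarray) -> dict[str, float]:
        p = dict(fixed)
        for n, v in zip(free_names, theta):
            p[n] = math.exp(v) if n in _LOG_PARAMS else float(v)
        return p

    lo = np.array(
        [
            math.log(box[n][0]) if n in _LOG_PARAMS else box[n][0]
            for n in free_names
        ]
    )
    hi = np.array(
        [
            math.log(box[n][1]) if n in _LOG_PARAMS else box[n][1]
            for n in free_names
        ]
    )

    target = traj.states

    def residuals(theta: np.ndarray) -> np.ndarray:
        model, x0 = _params_to_model(unpack(theta))
        pred = zero_input_response(model, x0, traj.times)
        return (pred.states - target).ravel()

    def solve(theta0: np.ndarray):
        return least_squares(
            residuals,
            np.clip(theta0, lo, hi),
            bounds=(lo, hi),
            ftol=FTOL,
            xtol=1e-12,
            gtol=1e-10,
            max_nfev=MAX_NFEV,
        )

    res = solve(pack(init_params))
    n_iter = res.nfev
    if res.status <= 0:
        # deterministic multi-start fallback: jitter the initialization
        rng = np.random.default_rng(0)
        best = res
        for _ in range(N_MULTISTART):
            jitter = rng.normal(0.0, 0.2, size=len(free_names))
            cand = solve(pack(init_params) + jitter)
            n_iter += cand.nfev
            if cand.cost < best.cost:
                best = cand
        res = best

    params = unpack(res.x)
    model, x0 = _params_to_model(params)
    m = target.size
    rms = float(np.sqrt(2.0 * res.cost / m))
    stderr = _curvature_stderr(res, free_names, params, m)
    return FitResult(
        estimate=model,
        initial_state_estimate=x0,
        residual_rms=rms,
        converged=bool(res.status > 0),
        n_iterations=int(n_iter),
        param_stderr=stderr,
        cost=float(res.cost),
    )


def _curvature_stderr(
    res, free_names: list[str], params: dict[str, float], m: int
) -> dict[str, float]:
    """Gauss-Newton standard errors from the Jacobian at the optimum."""
    p = len(free_names)
    dof = max(m - p, 1)
    sigma2 = 2.0 * res.cost / dof
    JtJ = res.jac.T @ res.jac
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    out: dict[str, float] = {}
    for i, n in enumerate(free_names):
        # delta method: parameters optimized as log(tau)
        out[n] = float(se[i] * params[n]) if n in _LOG_PARAMS else float(se[i])
    return out
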