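"""Vector field and trajectory integration for the repeat-silencing ODEs.

The model couples three first-order nonlinear equations::

    dx1/dt = alpha * x3 / (1 + x2/kappa1) - delta * x1
    dx2/dt = phi * [(x2/kappa2)/(1 + x2/kappa2)] * x2 * (x3 - x2)
             + eta * (x3 - x2) - mu * x2
    dx3/dt = sigma * x1 / (1 + x2/kappa3) - gamma * x3**2 / (1 + x2/kappa4)

Transcription is proportional to copy number and repressed by methylation;
methylation of U copies is spontaneous or cooperative (saturating in M);
new copies arise from reverse transcription of the transcript and are lost
by recombination, both repressed by methylation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ModelParameters, SystemState

__all__ = [
    "ode_rhs",
    "jacobian",
    "integrate",
    "default_initial_conditions",
    "Trajectory",
    "IntegrationError",
]

log = logging.getLogger(__name__)


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: np.ndarray, last_time: float):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


def _rhs(y, p: ModelParameters):
    """Raw right-hand side; algebra only, complex-safe (for complex-step
    differentiation), no validation."""
    x1, x2, x3 = y[0], y[1], y[2]
    sat = (x2 / p.kappa2) / (1.0 + x2 / p.kappa2)
    d1 = p.alpha * x3 / (1.0 + x2 / p.kappa1) - p.delta * x1
    d2 = p.phi * sat * x2 * (x3 - x2) + p.eta * (x3 - x2) - p.mu * x2
    d3 = p.sigma * x1 / (1.0 + x2 / p.kappa3) - p.gamma * x3 ** 2 / (1.0 + x2 / p.kappa4)
    return np.array([d1, d2, d3])


def ode_rhs(state, params: ModelParameters) -> np.ndarray:
    """Evaluate the vector field at ``state``.

    Parameters
    ----------
    state : SystemState or array-like of 3 floats
        Finite, non-negative (x1, x2, x3).
    params : ModelParameters

    Returns
    -------
    numpy.ndarray
        ``(dx1, dx2, dx3)``.  Pure function of its inputs.
    """
    if isinstance(state, SystemState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (3,):
            raise ValueError(f"state must have 3 components, got shape {y.shape}")
        for name, v in zip(("x1", "x2", "x3"), y):
            if not np.isfinite(v):
                raise ValueError(f"state component {name!r} is not finite: {v}")
    return _rhs(y, params)


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """3x3 Jacobian of the vector field, by complex-step differentiation.

    The right-hand side is a rational function of the state, so the
    complex-step derivative is exact to machine precision (no subtractive
    cancellation).
    """
    y = state.as_array() if isinstance(state, SystemState) else np.asarray(state, float)
    h = 1e-200
    J = np.empty((3, 3))
    for j in range(3):
        yc = y.astype(complex)
        yc[j] += 1j * h
        J[:, j] = np.imag(_rhs(yc, params)) / h
    return J


@dataclass
class Trajectory:
    """An integrated path of the ODE system.

    ``times`` and ``states`` (rows of (x1, x2, x3)) have equal length >= 2.
    ``converged`` is True iff the final state's derivative norm is below the
    strict steady-state tolerance.  ``min_component`` records the most
    negative value any component reached (the solver is not clipped; negative
    excursions beyond tolerance are reported, never silently altered).
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    converged: bool
    final_rhs_norm: float
    min_component: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def final_state(self) -> SystemState:
        y = np.maximum(self.states[-1], 0.0)  # tolerance-level negatives only
        return SystemState.from_array(y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "x1": self.states[:, 0],
             "x2": self.states[:, 1], "x3": self.states[:, 2]}
        )


def _polish(y: np.ndarray, params: ModelParameters) -> np.ndarray | None:
    """Newton-refine a near-steady endpoint to machine-precision residual.

    Returns None when the refined root is not a small correction of ``y``
    (the endpoint was not actually near a fixed point)."""
    sol = root(lambda z: _rhs(z, params), y, jac=lambda z: jacobian(z, params),
               method="hybr", tol=1e-13)
    # judge by the achieved residual, not the solver's progress flag (MINPACK
    # reports failure when xtol is tighter than the problem conditioning)
    resid = np.linalg.norm(_rhs(sol.x, params))
    if resid > 1e-10 * (1.0 + np.linalg.norm(sol.x)):
        return None
    scale = 1.0 + np.linalg.norm(y)
    if np.linalg.norm(sol.x - y) > 0.05 * scale:
        return None
    return sol.x


def integrate(
    params: ModelParameters,
    initial,
    horizon: float = 2e5,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    ss_tol: float = 1e-5,
    strict_ss_tol: float = 1e-9,
    method: str = "LSODA",
    polish: bool = True,
) -> Trajectory:
    """Integrate the ODEs from ``initial`` until steady state or ``horizon``.

    The default solver is ``LSODA`` (adaptive, with automatic stiffness
    switching): near an attractor an explicit pair's error noise can sit
    above the steady-state detection threshold while its stability bound
    caps the step size, turning slow final approaches into very long runs.
    An explicit low-order Runge-Kutta pair is available as
    ``method="RK23"`` and yields the same attractors.  Integration stops
    early when ``|f(y)| < ss_tol * (1 + |y|)``; the endpoint is then
    Newton-polished and declared converged when the polished residual
    satisfies the strict tolerance ``strict_ss_tol * (1 + |y|)``.

    Raises
    ------
    IntegrationError
        On solver failure (e.g. step-size underflow); carries the last
        valid state.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    y0 = initial.as_array() if isinstance(initial, SystemState) else np.asarray(initial, float)
    if y0.shape != (3,) or not np.all(np.isfinite(y0)):
        raise ValueError(f"initial state must be 3 finite components, got {y0}")

    def event(t, y, *_):
        f = _rhs(y, params)
        return float(np.linalg.norm(f) - ss_tol * (1.0 + np.linalg.norm(y)))

    event.terminal = True
    event.direction = -1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LSODA chatter on stiffness switches
        sol = solve_ivp(
            lambda t, y: _rhs(y, params), (0.0, horizon), y0,
            method=method, rtol=rtol, atol=atol, events=event,
        )
    if sol.status == -1:
        raise IntegrationError(
            f"integrator failed: {sol.message}", sol.y[:, -1], sol.t[-1]
        )

    times = sol.t
    states = sol.y.T
    min_comp = float(states.min()) if states.size else 0.0
    if min_comp < -100.0 * atol:
        log.warning("trajectory went negative beyond tolerance: min component %.3e", min_comp)
    x2_excess = float(np.max(states[:, 1] - states[:, 2]))
    if x2_excess > 100.0 * atol:
        log.warning("trajectory violated x2 <= x3 by up to %.3e", x2_excess)

    y_end = states[-1]
    near_steady = sol.status == 1 or event(times[-1], y_end) <= 0.0
    if polish and near_steady:
        refined = _polish(np.maximum(y_end, 0.0), params)
        if refined is not None:
            states = np.vstack([states, refined])
            times = np.append(times, times[-1])
    f_end = _rhs(states[-1], params)
    norm_end = float(np.linalg.norm(f_end))
    converged = norm_end < strict_ss_tol * (1.0 + np.linalg.norm(states[-1]))
    if len(times) < 2:  # degenerate: event fired at t=0
        times = np.append(times, times[-1])
        states = np.vstack([states, states[-1]])
    return Trajectory(
        times=times, states=states, params=params, converged=converged,
        final_rhs_norm=norm_end, min_component=min_comp,
        meta={"method": method, "rtol": rtol, "atol": atol,
              "ss_tol": ss_tol, "strict_ss_tol": strict_ss_tol,
              "x2_excess": x2_excess},
    )


def default_initial_conditions(params: ModelParameters) -> list[SystemState]:
    """Seven deterministic initial states probing the basins of attraction.

    Copy number is anchored at the unrepressed balance point
    ``sigma*alpha/(gamma*delta)`` (the CN nullcline value at x2 = 0) times
    {0.1, 1, 3}; the methylated fraction takes {0.05, 0.5, 0.95}; low/high
    copy number is crossed with low/high fraction plus intermediate points,
    and RNA starts at its quasi-steady-state value for each (x2, x3).
    """
    K = params.cn_scale
    combos = [
        (0.1, 0.05), (0.1, 0.5), (0.1, 0.95),
        (1.0, 0.5),
        (3.0, 0.05), (3.0, 0.5), (3.0, 0.95),
    ]
    out = []
    for c, f in combos:
        x3 = c * K
        x2 = f * x3
        x1 = params.alpha * x3 / (params.delta * (1.0 + x2 / params.kappa1))
        out.append(SystemState(x1, x2, x3))
    return out
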