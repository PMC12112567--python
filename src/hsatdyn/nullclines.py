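"""Quasi-steady-state reduction, nullclines, and steady-state analysis.

Transcription and RNA turnover act on a much faster time scale than
methylation or copy-number change, so RNA is taken to be equilibrated at
any (x2, x3):

    x1* = alpha * x3 / (delta * (1 + x2/kappa1))

Substituting x1* reduces the system to the (x2, x3) plane.  Setting
dx2/dt = 0 gives the M nullcline and, with x1*, setting dx3/dt = 0 gives
the CN nullcline (a nonzero branch plus the x3 = 0 branch).  Intersections
of the two nullclines are the steady states of the reduced system; one
interior intersection means monostability, three mean bistability via a
saddle-node bifurcation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import _rhs, jacobian
from .params import ModelParameters, SystemState

__all__ = [
    "rna_qssa",
    "m_nullcline",
    "cn_nullcline",
    "nullcline_curves",
    "find_steady_states",
    "SteadyState",
    "NullclineCurve",
]

log = logging.getLogger(__name__)


def rna_qssa(x2, x3, params: ModelParameters):
    """Quasi-steady-state RNA level x1* = alpha*x3 / (delta*(1 + x2/kappa1)).

    Accepts scalars or arrays; pure algebraic evaluation.
    """
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    out = params.alpha * x3 / (params.delta * (1.0 + x2 / params.kappa1))
    return float(out) if out.ndim == 0 else out


def m_nullcline(x2, params: ModelParameters):
    """Copy number x3 on the M nullcline (dx2/dt = 0) at methylated count x2.

    x3 = [phi*s*x2^2 + (eta + mu)*x2] / [phi*s*x2 + eta]  with
    s = (x2/kappa2)/(1 + x2/kappa2).  Requires eta > 0 so the denominator
    is strictly positive; x2 = 0 maps to x3 = 0.
    """
    if params.eta <= 0:
        raise ValueError("m_nullcline requires eta > 0 (singular at x2 = 0 otherwise)")
    x2 = np.asarray(x2, dtype=float)
    s = (x2 / params.kappa2) / (1.0 + x2 / params.kappa2)
    num = params.phi * s * x2 ** 2 + (params.eta + params.mu) * x2
    den = params.phi * s * x2 + params.eta
    out = num / den
    return float(out) if out.ndim == 0 else out


def cn_nullcline(x2, params: ModelParameters):
    """Copy number x3 on the nonzero branch of the CN nullcline (dx3/dt = 0).

    x3 = (sigma*alpha/(gamma*delta)) * (1 + x2/kappa4)
         / [(1 + x2/kappa1)(1 + x2/kappa3)]

    The additional branch x3 = 0 always exists and carries the origin
    steady state.
    """
    x2 = np.asarray(x2, dtype=float)
    K = params.cn_scale
    out = K * (1.0 + x2 / params.kappa4) / (
        (1.0 + x2 / params.kappa1) * (1.0 + x2 / params.kappa3)
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NullclineCurve:
    """A nullcline evaluated on an x2 grid."""

    which: Literal["M", "CN-nonzero", "CN-zero"]
    x2: np.ndarray
    x3: np.ndarray
    params: ModelParameters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x2": self.x2, "x3": self.x3, "nullcline": self.which})


def nullcline_curves(
    params: ModelParameters, x2_max: float | None = None, n: int = 500
) -> tuple[NullclineCurve, NullclineCurve]:
    """Evaluate the M and nonzero-CN nullclines on a shared log-spaced grid."""
    if x2_max is None:
        x2_max = 10.0 * params.cn_scale
    x2 = np.logspace(np.log10(1e-6 * params.cn_scale), np.log10(x2_max), n)
    return (
        NullclineCurve("M", x2, m_nullcline(x2, params), params),
        NullclineCurve("CN-nonzero", x2, cn_nullcline(x2, params), params),
    )


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the full 3D system with its linear classification."""

    state: SystemState
    stable: bool
    branch: Literal["silenced", "desilenced"]
    eigenvalues: tuple[complex, complex, complex]
    marginal: bool = False

    @property
    def methylated_fraction(self) -> float:
        return self.state.methylated_fraction


def _classify(x1: float, x2: float, x3: float, params: ModelParameters,
              marginal: bool = False) -> SteadyState:
    st = SystemState(max(x1, 0.0), max(x2, 0.0), max(x3, 0.0))
    ev = np.linalg.eigvals(jacobian(st, params))
    stable = bool(np.all(ev.real < 0.0))
    frac = st.methylated_fraction
    branch = "silenced" if (np.isfinite(frac) and frac >= 0.5) else "desilenced"
    return SteadyState(st, stable, branch, tuple(ev), marginal)


def find_steady_states(
    params: ModelParameters,
    x2_max: float | None = None,
    *,
    n_grid: int = 2000,
    include_origin: bool = True,
    residual_tol: float = 1e-8,
) -> list[SteadyState]:
    """Locate all steady states as nullcline intersections.

    Sign changes of ``m_nullcline - cn_nullcline`` are bracketed on a dense
    log-spaced x2 grid and refined by Brent root-finding; near-tangent
    non-crossing minima trigger a local grid refinement so fold points are
    not missed.  Each interior root is lifted to 3D via the RNA
    quasi-steady state, residual-checked against the full vector field, and
    classified by the eigenvalues of the 3D Jacobian.  The origin (x3 = 0
    branch) is always included; for x2 > 0 the M nullcline lies strictly
    above the diagonal, so the zero branch carries no other intersection.

    Returns states sorted by x2 (origin first).
    """
    K = params.cn_scale
    if x2_max is None:
        x2_max = 10.0 * K

    def g(x2: float) -> float:
        return m_nullcline(x2, params) - cn_nullcline(x2, params)

    lo = 1e-6 * K
    grid = np.logspace(np.log10(lo), np.log10(x2_max), n_grid)
    vals = np.asarray(m_nullcline(grid, params) - cn_nullcline(grid, params))

    brackets: list[tuple[float, float]] = []
    sign = np.sign(vals)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        brackets.append((grid[i], grid[i + 1]))
    # near-tangency rescue: refine around interior local minima of |g| that
    # do not bracket a sign change (possible pair of close roots)
    absv = np.abs(vals)
    for i in range(1, len(grid) - 1):
        if absv[i] < absv[i - 1] and absv[i] < absv[i + 1] and sign[i - 1] == sign[i + 1]:
            fine = np.logspace(np.log10(grid[i - 1]), np.log10(grid[i + 1]), 200)
            fv = np.asarray(m_nullcline(fine, params) - cn_nullcline(fine, params))
            fs = np.sign(fv)
            for j in np.flatnonzero(fs[:-1] * fs[1:] < 0):
                brackets.append((fine[j], fine[j + 1]))

    roots: list[float] = []
    for a, b in sorted(brackets):
        r = brentq(g, a, b, xtol=1e-13, rtol=4 * np.finfo(float).eps)
        if not roots or abs(r - roots[-1]) > 1e-8 * (1.0 + abs(r)):
            roots.append(r)

    out: list[SteadyState] = []
    if include_origin:
        out.append(_classify(0.0, 0.0, 0.0, params))
    for r in roots:
        x3 = m_nullcline(r, params)
        x1 = rna_qssa(r, x3, params)
        resid = np.linalg.norm(_rhs(np.array([x1, r, x3]), params))
        scale = np.linalg.norm([x1, r, x3])
        if resid > residual_tol * (1.0 + scale):
            log.warning("discarding spurious intersection at x2=%.4g (residual %.2e)", r, resid)
            continue
        # fold-point flag: |d(g)/dx2| ~ 0 at the root means a marginal
        # (saddle-node) intersection
        h = 1e-6 * (1.0 + r)
        dg = (g(r + h) - g(max(r - h, 0.0))) / (2 * h)
        gscale = (abs(m_nullcline(r, params)) + abs(cn_nullcline(r, params))) / (1.0 + r)
        marginal = abs(dg) < 1e-6 * (1.0 + gscale)
        out.append(_classify(x1, r, x3, params, marginal=marginal))
    return out
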