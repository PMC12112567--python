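"""Regime classification over 1D parameter ranges and 2D parameter pairs.

Each parameter (or pair) is varied around the calibrated reference while
all others stay fixed, and every grid point is classified as silenced
monostable, desilenced monostable, or bistable by multi-start integration.
Grids are expressed as normalized values (parameter / reference value), so
1 always marks the reference set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bifurcation import deduplicate_states
from .model import default_initial_conditions, integrate
from .nullclines import find_steady_states
from .params import ModelParameters

__all__ = ["classify_regime", "scan_1d", "scan_2d", "RegimeMap"]

log = logging.getLogger(__name__)

REGIMES = ("silenced", "desilenced", "bistable", "undetermined")


def classify_regime(
    params: ModelParameters,
    *,
    method: str = "integration",
    fraction_threshold: float = 0.5,
    horizon: float = 2e5,
    **integrate_opts,
) -> str:
    """Classify ``params`` as silenced / desilenced / bistable / undetermined.

    ``method="integration"`` (default) integrates the seven default initial
    conditions and deduplicates the converged endpoints: two or more
    distinct stable states mean bistability, one means monostability
    labeled by its methylated fraction against ``fraction_threshold``.
    Any non-convergent start yields "undetermined".

    ``method="nullclines"`` classifies from the interior nullcline
    intersections instead (fast, used for cross-validation).
    """
    if method == "nullclines":
        stable = [s for s in find_steady_states(params, include_origin=False) if s.stable]
        if len(stable) >= 2:
            return "bistable"
        if len(stable) == 1:
            f = stable[0].methylated_fraction
            return "silenced" if f >= fraction_threshold else "desilenced"
        return "undetermined"
    if method != "integration":
        raise ValueError(f"unknown method {method!r}")

    endpoints = []
    for ic in default_initial_conditions(params):
        try:
            tr = integrate(params, ic, horizon, **integrate_opts)
        except Exception:
            return "undetermined"
        if not tr.converged:
            return "undetermined"
        endpoints.append(tr.final_state.as_array())
    stable = deduplicate_states(endpoints)
    if len(stable) >= 2:
        return "bistable"
    y = stable[0]
    frac = y[1] / y[2] if y[2] > 0 else 0.0
    return "silenced" if frac >= fraction_threshold else "desilenced"


@dataclass
class RegimeMap:
    """Regime labels over a normalized 1D range or 2D grid."""

    parameters: tuple[str, ...]
    #: normalized grids (value / reference value), one per axis
    grids: tuple[np.ndarray, ...]
    #: regime labels; shape (n,) for 1D, (n_a, n_b) for 2D
    regimes: np.ndarray
    reference: ModelParameters
    meta: dict = field(default_factory=dict)

    def intervals(self) -> list[tuple[str, float, float]]:
        """Contiguous (regime, lo, hi) runs of a 1D scan, in normalized units."""
        if len(self.parameters) != 1:
            raise ValueError("intervals() applies to 1D scans only")
        g = self.grids[0]
        out = []
        start = 0
        r = self.regimes
        for i in range(1, len(g) + 1):
            if i == len(g) or r[i] != r[start]:
                out.append((str(r[start]), float(g[start]), float(g[i - 1])))
                start = i
        return out

    def to_frame(self) -> pd.DataFrame:
        if len(self.parameters) == 1:
            return pd.DataFrame({
                "parameter": self.parameters[0],
                "normalized_value": self.grids[0],
                "regime": self.regimes,
            })
        a, b = np.meshgrid(self.grids[0], self.grids[1], indexing="ij")
        return pd.DataFrame({
            f"normalized_{self.parameters[0]}": a.ravel(),
            f"normalized_{self.parameters[1]}": b.ravel(),
            "regime": self.regimes.ravel(),
        })


def _normalized_grid(span: tuple[float, float], n: int) -> np.ndarray:
    lo, hi = span
    if not (0 < lo < 1 < hi):
        raise ValueError("normalized range must span the reference value 1")
    return np.logspace(np.log10(lo), np.log10(hi), n)


def scan_1d(
    params: ModelParameters,
    name: str,
    normalized_range: tuple[float, float] = (1e-2, 1e2),
    n: int = 41,
    **classify_opts,
) -> RegimeMap:
    """Classify the regime along one parameter's normalized range."""
    if name not in params.to_dict():
        raise KeyError(f"unknown parameter {name!r}")
    grid = _normalized_grid(normalized_range, n)
    regimes = np.array(
        [classify_regime(params.scaled(name, float(f)), **classify_opts) for f in grid],
        dtype=object,
    )
    return RegimeMap((name,), (grid,), regimes, params)


def scan_2d(
    params: ModelParameters,
    name_a: str,
    name_b: str,
    normalized_range_a: tuple[float, float] = (1e-2, 1e2),
    normalized_range_b: tuple[float, float] = (1e-2, 1e2),
    n_a: int = 15,
    n_b: int = 15,
    **classify_opts,
) -> RegimeMap:
    """Classify the regime over a 2D grid of two distinct parameters."""
    for nm in (name_a, name_b):
        if nm not in params.to_dict():
            raise KeyError(f"unknown parameter {nm!r}")
    if name_a == name_b:
        raise ValueError("the two scanned parameters must be distinct")
    ga = _normalized_grid(normalized_range_a, n_a)
    gb = _normalized_grid(normalized_range_b, n_b)
    regimes = np.empty((n_a, n_b), dtype=object)
    for i, fa in enumerate(ga):
        p_row = params.scaled(name_a, float(fa))
        for j, fb in enumerate(gb):
            regimes[i, j] = classify_regime(p_row.scaled(name_b, float(fb)), **classify_opts)
    return RegimeMap((name_a, name_b), (ga, gb), regimes, params)
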