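"""Bifurcation diagrams by multi-start integration, branch labeling, hysteresis.

A diagram is built the way it would be measured: for each value of the
swept parameter the ODEs are integrated from the seven default initial
conditions, converged endpoints are deduplicated into the set of reachable
stable states, and the count is cross-validated against the nullcline
intersections.  Branches are labeled silenced/desilenced by 2-means
clustering of the methylated fraction pooled over the whole sweep, the
lower-methylation cluster being the desilenced branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .model import default_initial_conditions, integrate
from .nullclines import find_steady_states
from .params import ModelParameters, SystemState

__all__ = [
    "sweep_parameter",
    "label_branches",
    "hysteresis_scan",
    "deduplicate_states",
    "BifurcationResult",
    "HysteresisResult",
]

log = logging.getLogger(__name__)

#: relative distance below which two converged states are the same attractor,
#: measured in (methylated fraction, log copy number) coordinates
DEDUP_TOL = 1e-4


def _embed(y: np.ndarray) -> np.ndarray:
    """(x1,x2,x3) -> (x2/x3, log x3) with a guarded zero copy number."""
    x3 = max(float(y[2]), 1e-300)
    frac = float(y[1]) / x3 if y[2] > 0 else 0.0
    return np.array([frac, np.log(x3)])


def deduplicate_states(states: list[np.ndarray], tol: float = DEDUP_TOL) -> list[np.ndarray]:
    """Collapse converged endpoints that correspond to the same attractor."""
    reps: list[np.ndarray] = []
    for y in states:
        e = _embed(y)
        for r in reps:
            if np.linalg.norm(e - _embed(r)) < tol * (1.0 + np.linalg.norm(_embed(r))):
                break
        else:
            reps.append(np.asarray(y, dtype=float))
    return reps


def label_branches(fractions) -> tuple[list[str], dict]:
    """Label steady states silenced/desilenced from their methylated fractions.

    1D k-means with k = 2 on the pooled fractions; when the two centroids
    differ by less than 0.05 the sweep is declared single-branch and every
    state is labeled by its fraction against 0.5.  Otherwise each state
    takes the label of its nearest centroid, the lower-methylation cluster
    being "desilenced".

    Returns (labels, info) where info carries the centroids and the
    single-branch flag.
    """
    f = np.asarray(list(fractions), dtype=float)
    if f.size == 0:
        raise ValueError("label_branches requires at least one steady state")
    if f.size == 1 or np.ptp(f) == 0.0:
        lab = "silenced" if f[0] >= 0.5 else "desilenced"
        return [lab] * f.size, {"single_branch": True, "centroids": (float(f[0]),) * 2}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence chatter
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(f.reshape(-1, 1))
    c = np.sort(km.cluster_centers_.ravel())
    if c[1] - c[0] < 0.05:
        labels = ["silenced" if x >= 0.5 else "desilenced" for x in f]
        return labels, {"single_branch": True, "centroids": (float(c[0]), float(c[1]))}
    thr = float(c.mean())
    labels = ["silenced" if x >= thr else "desilenced" for x in f]
    return labels, {"single_branch": False, "centroids": (float(c[0]), float(c[1])),
                    "threshold": thr}


@dataclass
class BifurcationResult:
    """Steady states and regime labels along a one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    #: per grid point, list of (SystemState, stable) reachable/known states
    states: list[list[tuple[SystemState, bool]]]
    #: per grid point: silenced | desilenced | bistable | undetermined
    regimes: list[str]
    #: per state, aligned with `states` flattened: branch labels
    branches: list[list[str]]
    #: grid points where integration and nullcline counts disagreed
    flagged: list[int] = field(default_factory=list)
    reference: ModelParameters | None = None
    clustering: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(self.grid):
            for (st, stable), br in zip(self.states[i], self.branches[i]):
                rows.append(
                    {"parameter": self.parameter, "parameter_value": v,
                     "x1": st.x1, "x2": st.x2, "x3": st.x3,
                     "methylated_fraction": st.methylated_fraction,
                     "stability": "stable" if stable else "unstable",
                     "branch": br, "regime": self.regimes[i]}
                )
        return pd.DataFrame(rows)


def sweep_parameter(
    params: ModelParameters,
    name: str,
    grid,
    *,
    include_unstable: bool = True,
    horizon: float = 2e5,
    **integrate_opts,
) -> BifurcationResult:
    """Build a bifurcation diagram for ``name`` over ``grid``.

    For each grid value the seven default initial conditions are integrated
    to steady state; distinct converged endpoints are the stable states.
    The stable-state count is cross-validated against the nullcline
    intersections (mismatches are flagged, not fatal).  Unstable interior
    states from the nullcline analysis are included for a complete diagram
    unless ``include_unstable`` is False.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    if name not in params.to_dict():
        raise KeyError(f"unknown parameter {name!r}")

    per_point: list[list[tuple[SystemState, bool]]] = []
    regimes: list[str] = []
    flagged: list[int] = []
    for i, v in enumerate(grid):
        p = params.replace(**{name: float(v)})
        endpoints = []
        any_fail = False
        for ic in default_initial_conditions(p):
            try:
                tr = integrate(p, ic, horizon, **integrate_opts)
            except Exception:  # numerical failure at one start: flag, continue
                any_fail = True
                continue
            if tr.converged:
                endpoints.append(tr.final_state.as_array())
            else:
                any_fail = True
        stable = deduplicate_states(endpoints)
        nc = find_steady_states(p, include_origin=False)
        nc_stable = [s for s in nc if s.stable]
        if len(stable) != len(nc_stable):
            flagged.append(i)
            log.warning(
                "%s=%.4g: %d stable endpoints vs %d stable nullcline intersections",
                name, v, len(stable), len(nc_stable),
            )
        entry = [(SystemState.from_array(np.maximum(y, 0.0)), True) for y in stable]
        if include_unstable:
            entry += [(s.state, False) for s in nc if not s.stable]
        entry.sort(key=lambda t: t[0].x2)
        per_point.append(entry)
        if any_fail and not stable:
            regimes.append("undetermined")
        elif len(stable) >= 2:
            regimes.append("bistable")
        elif len(stable) == 1:
            frac = stable[0][1] / stable[0][2] if stable[0][2] > 0 else 0.0
            regimes.append("silenced" if frac >= 0.5 else "desilenced")
        else:
            regimes.append("undetermined")

    pooled = [st.methylated_fraction for entry in per_point for st, _ in entry]
    if pooled:
        labels, info = label_branches(pooled)
    else:
        labels, info = [], {}
    branches: list[list[str]] = []
    k = 0
    for entry in per_point:
        branches.append(labels[k:k + len(entry)])
        k += len(entry)
    return BifurcationResult(name, grid, per_point, regimes, branches,
                             flagged, params, info)


@dataclass
class HysteresisResult:
    """Forward and backward continuation traces over a parameter grid."""

    parameter: str
    grid: np.ndarray
    forward: np.ndarray   # (n, 3) steady states following the grid upward
    backward: np.ndarray  # (n, 3) aligned with `grid`, traversed downward

    def loop_gap(self) -> np.ndarray:
        """Relative distance between the two traces at each grid point."""
        num = np.linalg.norm(self.forward - self.backward, axis=1)
        den = 1.0 + np.linalg.norm(self.forward, axis=1)
        return num / den

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, trace in (("forward", self.forward), ("backward", self.backward)):
            for v, y in zip(self.grid, trace):
                rows.append({"parameter": self.parameter, "parameter_value": v,
                             "direction": direction, "x1": y[0], "x2": y[1], "x3": y[2]})
        return pd.DataFrame(rows)


def hysteresis_scan(
    params: ModelParameters,
    name: str,
    grid,
    *,
    horizon: float = 2e5,
    **integrate_opts,
) -> HysteresisResult:
    """Continuation-style sweep: each converged state seeds the next grid value.

    The forward pass starts from the steady state reached from the
    intermediate default initial condition at ``grid[0]`` and follows the
    attractor as the parameter increases; the backward pass starts from the
    forward endpoint and retraces the grid downward.  Inside a bistable
    window the two traces land on different branches (hysteresis loop).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive, strictly increasing, length >= 2")

    def settle(p: ModelParameters, y0) -> np.ndarray:
        tr = integrate(p, y0, horizon, **integrate_opts)
        if not tr.converged:
            log.warning("%s=%.4g: continuation point did not converge", name, 0)
        return tr.final_state.as_array()

    p0 = params.replace(**{name: float(grid[0])})
    y = settle(p0, default_initial_conditions(p0)[3])
    fwd = []
    for v in grid:
        y = settle(params.replace(**{name: float(v)}), y)
        fwd.append(y)
    bwd = [None] * len(grid)
    for i in range(len(grid) - 1, -1, -1):
        y = settle(params.replace(**{name: float(grid[i])}), y)
        bwd[i] = y
    return HysteresisResult(name, grid, np.array(fwd), np.array(bwd))
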