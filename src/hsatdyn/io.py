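"""Result serialization and provenance sidecars.

Every command-line run writes tidy CSV tables plus a ``sidecar.json``
capturing the resolved parameters, tolerances and package version, so any
output directory is re-creatable from its sidecar alone (bit-for-bit on
deterministic paths, distribution-for-distribution with the same seed on
stochastic ones).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .bifurcation import BifurcationResult, HysteresisResult
from .model import Trajectory
from .nullclines import SteadyState, nullcline_curves
from .params import ModelParameters
from .sensitivity import RegimeMap

__all__ = [
    "write_sidecar",
    "write_trajectory",
    "write_steady_states",
    "write_nullclines",
    "write_bifurcation",
    "write_regime_map",
]


def write_sidecar(outdir: str | Path, config: dict) -> Path:
    """Write the provenance sidecar for an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"package": "hsatdyn", "version": __version__, **config}
    path = outdir / "sidecar.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")
    return path


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    return path


def steady_states_frame(states: list[SteadyState]) -> pd.DataFrame:
    rows = []
    for s in states:
        rows.append({
            "x1": s.state.x1, "x2": s.state.x2, "x3": s.state.x3,
            "methylated_fraction": s.methylated_fraction,
            "stability": "stable" if s.stable else "unstable",
            "branch": s.branch, "marginal": s.marginal,
            "eig_re_1": s.eigenvalues[0].real,
            "eig_re_2": s.eigenvalues[1].real,
            "eig_re_3": s.eigenvalues[2].real,
        })
    return pd.DataFrame(rows)


def write_steady_states(states: list[SteadyState], path: str | Path) -> Path:
    path = Path(path)
    steady_states_frame(states).to_csv(path, index=False)
    return path


def write_nullclines(params: ModelParameters, path: str | Path,
                     x2_max: float | None = None, n: int = 500) -> Path:
    m_curve, cn_curve = nullcline_curves(params, x2_max, n)
    df = pd.DataFrame({
        "x2": m_curve.x2,
        "x3_m_nullcline": m_curve.x3,
        "x3_cn_nullcline": cn_curve.x3,
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_bifurcation(result: BifurcationResult | HysteresisResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    return path


def write_regime_map(result: RegimeMap, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    return path
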