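"""Parameter and state containers for the repeat-silencing ODE model.

The model tracks three quantities at a pericentromeric satellite array:
``x1`` — the number of lncRNA transcripts, ``x2`` — the number of
methylated (silenced) repeat copies M, and ``x3`` — the total repeat
copy number CN.  Unmethylated copies are ``U = x3 - x2``.  Eleven kinetic
constants govern transcription, RNA turnover, methylation/demethylation,
reverse-transcription insertion and recombination deletion; all rates are
expressed per generation (the model carries no absolute time unit).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = ["ModelParameters", "SystemState", "PARAMETER_NAMES"]

#: Canonical parameter order used in configs, CSV output and sweeps.
PARAMETER_NAMES = (
    "alpha", "delta", "phi", "eta", "mu",
    "sigma", "gamma", "kappa1", "kappa2", "kappa3", "kappa4",
)


@dataclass(frozen=True)
class ModelParameters:
    """The eleven kinetic constants of the silencing/copy-number ODEs.

    Attributes
    ----------
    alpha : float
        Transcription rate per unrepressed repeat copy (RNA * copy^-1 * gen^-1).
    delta : float
        RNA degradation rate (gen^-1).
    phi : float
        Cooperative methylation rate; acts through the saturating
        M-dependent term (copy^-1 * gen^-1).
    eta : float
        Spontaneous methylation rate of U copies (gen^-1).
    mu : float
        Demethylation rate of M copies (gen^-1).
    sigma : float
        Reverse-transcription insertion rate (copy * RNA^-1 * gen^-1).
    gamma : float
        Recombination deletion rate (copy^-1 * gen^-1).
    kappa1 : float
        Half-repression scale of transcription by M (copies).
    kappa2 : float
        Half-saturation scale of cooperative methylation in M (copies).
    kappa3 : float
        Half-repression scale of reverse transcription by M (copies).
    kappa4 : float
        Half-repression scale of recombination by M (copies).
    """

    alpha: float
    delta: float
    phi: float
    eta: float
    mu: float
    sigma: float
    gamma: float
    kappa1: float
    kappa2: float
    kappa3: float
    kappa4: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"parameter {f.name!r} must be a number, got {v!r}")
            v = float(v)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive and finite, got {v}"
                )
            object.__setattr__(self, f.name, v)

    # -- derived scales -------------------------------------------------

    @property
    def cn_scale(self) -> float:
        """Copy number of the unrepressed balance point sigma*alpha/(gamma*delta).

        This is the value of the nonzero CN nullcline at ``x2 = 0`` and sets
        the natural copy-number scale of the system.
        """
        return self.sigma * self.alpha / (self.gamma * self.delta)

    # -- mutation helpers -----------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given parameters replaced."""
        d = self.to_dict()
        for k in changes:
            if k not in d:
                raise KeyError(f"unknown parameter {k!r}")
        d.update(changes)
        return ModelParameters(**d)

    def scaled(self, name: str, factor: float) -> "ModelParameters":
        """Return a copy with parameter ``name`` multiplied by ``factor``."""
        return self.replace(**{name: getattr(self, name) * factor})

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParameters":
        unknown = set(data) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(data)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(data[k]) for k in PARAMETER_NAMES})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load parameters from a YAML or JSON file (strict keys)."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"parameter file {path} must hold a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class SystemState:
    """One point of the 3D state space (x1 RNA, x2 methylated, x3 total copies).

    All components are continuous and non-negative.  ``x2 <= x3`` is the
    biologically meaningful region; the ODE does not structurally preserve
    it, so integration monitors rather than enforces the inequality.
    """

    x1: float
    x2: float
    x3: float

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"state component {name!r} is not finite: {v}")
            if v < 0.0:
                raise ValueError(f"state component {name!r} is negative: {v}")
            object.__setattr__(self, name, v)

    @property
    def methylated_fraction(self) -> float:
        """x2 / x3; NaN at zero copy number."""
        return self.x2 / self.x3 if self.x3 > 0 else math.nan

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "SystemState":
        a = np.asarray(list(arr), dtype=float)
        if a.shape != (3,):
            raise ValueError(f"state array must have 3 components, got shape {a.shape}")
        return cls(*a)
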