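"""Stochastic spatial model: a 1D chain of U/M repeat monomers.

Each repeat unit of the satellite array is a monomer in a chain and is
either unmethylated (U) or methylated (M).  Once per generation, from the
current configuration alone (the process is Markovian):

* every M demethylates with probability ``mu``;
* every U methylates spontaneously with probability ``eta``; a U with at
  least one M within ``neighborhood_radius`` (two repeats) positions is
  additionally eligible for cooperative methylation (``phi``), the two
  chances composing independently to ``1 - (1-eta)(1-phi)``;
* the transcript level is ``alpha*CN / (delta*(1 + nM/kappa))``; a
  Poisson-distributed number of new U monomers with mean
  ``sigma*n_transcript / (1 + nM/kappa3)`` is inserted, each adjacent to a
  uniformly chosen U site (reverse transcription inserts at active
  repeats);
* a Poisson number with mean ``gamma*CN**2 / (1 + nM/kappa4)`` of
  uniformly chosen U sites is deleted (recombination between active
  repeats), capped at the available U count.

State flips are computed from the pre-update chain; insertions and then
deletions are applied afterwards.  Runs are bit-reproducible given the
seed, the parameters and the initial chain.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .params import ModelParameters

__all__ = [
    "SpatialParameters",
    "RepeatChain",
    "step",
    "run",
    "SpatialRun",
    "m_domains",
    "phase_grid",
    "mean_field_increments",
    "transcript_level",
]

log = logging.getLogger(__name__)

#: demonstration regime: long chain with a majority-methylated start
DEFAULT_CHAIN_LENGTH = 15_000
DEFAULT_INIT_FRACTION = 0.68


@dataclass(frozen=True)
class SpatialParameters:
    """Per-generation rates and scales of the chain model.

    ``eta``, ``phi`` and ``mu`` are probabilities per site per generation.
    The transcript/insertion/deletion constants play the same roles as in
    the ODE model; their defaults are calibrated so the demonstration chain
    (15,000 repeats, 68 % methylated) holds a quasi-steady copy number of
    order 10^4.  ``neighborhood_radius`` is the cooperative range in
    repeats (2), or ``"global"`` for mean-field cooperativity where every U
    is eligible whenever any M exists.
    """

    eta: float = 0.01
    phi: float = 0.2
    mu: float = 0.1
    alpha: float = 1.0
    delta: float = 1.0
    kappa: float = 1000.0
    sigma: float = 0.5
    kappa3: float = 1000.0
    gamma: float = 4.5e-7
    kappa4: float = 10000.0
    neighborhood_radius: int | str = 2

    def __post_init__(self) -> None:
        for name in ("eta", "phi", "mu"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} is a probability, got {v}")
        for name in ("alpha", "delta", "kappa", "sigma", "kappa3", "gamma", "kappa4"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        r = self.neighborhood_radius
        if r != "global" and (not isinstance(r, int) or r < 1):
            raise ValueError("neighborhood_radius must be a positive integer or 'global'")

    @property
    def methylation_probability_eligible(self) -> float:
        """Composed per-generation U->M probability for a cooperative-eligible U."""
        return 1.0 - (1.0 - self.eta) * (1.0 - self.phi)

    def replace(self, **changes) -> "SpatialParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def transcript_level(n_methylated: int, copy_number: int, params: SpatialParameters) -> float:
    """lncRNA level alpha*CN / (delta*(1 + nM/kappa)) for the current chain."""
    return params.alpha * copy_number / (params.delta * (1.0 + n_methylated / params.kappa))


@dataclass
class RepeatChain:
    """Ordered U/M states plus the generation counter and the RNG stream.

    ``states`` is a boolean array, True = M.  The chain owns its random
    stream: ``seed`` plus the stream position (the bit-generator state)
    make trajectories bit-reproducible; :func:`step` consumes randomness
    from this stream.
    """

    states: np.ndarray
    generation: int = 0
    seed: int | None = None
    rng: np.random.Generator = None  # type: ignore[assignment]
    extinct: bool = False
    #: events of the step that produced this chain (transcripts, insertions, deletions)
    last_events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 1:
            raise ValueError("chain states must be one-dimensional")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    # -- constructors ----------------------------------------------------

    @classmethod
    def random(cls, length: int, methylated_fraction: float, seed: int) -> "RepeatChain":
        """A chain of ``length`` sites, each M independently with the given fraction."""
        rng = np.random.default_rng(seed)
        states = rng.random(length) < methylated_fraction
        return cls(states, 0, seed, rng)

    @classmethod
    def default(cls, seed: int = 0) -> "RepeatChain":
        return cls.random(DEFAULT_CHAIN_LENGTH, DEFAULT_INIT_FRACTION, seed)

    # -- observables -----------------------------------------------------

    @property
    def copy_number(self) -> int:
        return int(self.states.size)

    @property
    def n_methylated(self) -> int:
        return int(self.states.sum())

    @property
    def methylated_fraction(self) -> float:
        return self.n_methylated / self.copy_number if self.copy_number else math.nan

    # -- serialization ---------------------------------------------------

    def to_rle(self) -> str:
        """Run-length encoding, e.g. ``"M12U3M40"`` (empty chain -> '')."""
        if self.copy_number == 0:
            return ""
        out = []
        s = self.states
        changes = np.flatnonzero(np.diff(s)) + 1
        bounds = np.concatenate(([0], changes, [s.size]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            out.append(("M" if s[a] else "U") + str(b - a))
        return "".join(out)

    @classmethod
    def from_rle(cls, rle: str, generation: int = 0, seed: int | None = None) -> "RepeatChain":
        parts = re.findall(r"([MU])(\d+)", rle)
        if "".join(f"{s}{n}" for s, n in parts) != rle.strip():
            raise ValueError(f"malformed run-length encoding: {rle!r}")
        segs = [np.full(int(n), s == "M", dtype=bool) for s, n in parts]
        states = np.concatenate(segs) if segs else np.zeros(0, dtype=bool)
        return cls(states, generation, seed)

    def to_dict(self) -> dict:
        return {"rle": self.to_rle(), "generation": self.generation,
                "seed": self.seed, "rng_state": self.rng.bit_generator.state,
                "extinct": self.extinct}

    @classmethod
    def from_dict(cls, d: dict) -> "RepeatChain":
        ch = cls.from_rle(d["rle"], d["generation"], d.get("seed"))
        ch.rng.bit_generator.state = d["rng_state"]
        ch.extinct = bool(d.get("extinct", False))
        return ch


def _cooperative_eligibility(states: np.ndarray, radius: int | str) -> np.ndarray:
    """True where a site has at least one M within ``radius`` positions."""
    n = states.size
    if radius == "global":
        return np.full(n, states.any())
    padded = np.zeros(n + 2 * radius, dtype=bool)
    padded[radius:radius + n] = states
    elig = np.zeros(n, dtype=bool)
    for off in range(-radius, radius + 1):
        if off == 0:
            continue
        elig |= padded[radius + off: radius + off + n]
    return elig


def step(chain: RepeatChain, params: SpatialParameters) -> RepeatChain:
    """Advance the chain one generation (synchronous update).

    Randomness is drawn from the chain's stream in a fixed order (flips,
    insertion count, insertion placement, deletion count, deletion sites),
    so trajectories are reproducible.  A zero-length chain is returned
    unchanged except for the extinction flag.
    """
    rng = chain.rng
    s = chain.states
    cn = chain.copy_number
    if cn == 0:
        return RepeatChain(s, chain.generation + 1, chain.seed, rng, extinct=True)

    n_m = chain.n_methylated
    ntr = transcript_level(n_m, cn, params)

    # (2) per-site flips from the current configuration
    elig = _cooperative_eligibility(s, params.neighborhood_radius)
    p_um = np.where(elig, params.methylation_probability_eligible, params.eta)
    u = rng.random(cn)
    new = np.where(s, u >= params.mu, u < p_um)

    events = {"transcripts": ntr, "insertions": 0, "deletions": 0}

    # (3) reverse-transcription insertions: new U monomers adjacent to U hosts
    lam_ins = params.sigma * ntr / (1.0 + n_m / params.kappa3)
    n_ins = int(rng.poisson(lam_ins))
    if n_ins:
        hosts = np.flatnonzero(~new)
        if hosts.size == 0:
            log.info("generation %d: %d insertions skipped (no U host sites)",
                     chain.generation, n_ins)
        else:
            picked = rng.choice(hosts, size=n_ins)
            side = rng.integers(0, 2, size=n_ins)
            new = np.insert(new, np.sort(picked + side), False)
            events["insertions"] = n_ins

    # (4) recombination deletions of U sites, capped at the available U count
    lam_del = params.gamma * cn ** 2 / (1.0 + n_m / params.kappa4)
    n_del = int(rng.poisson(lam_del))
    if n_del:
        usites = np.flatnonzero(~new)
        n_del = min(n_del, usites.size)
        if n_del:
            kill = rng.choice(usites, size=n_del, replace=False)
            new = np.delete(new, kill)
            events["deletions"] = n_del

    return RepeatChain(new, chain.generation + 1, chain.seed, rng,
                       extinct=(new.size == 0), last_events=events)


@dataclass
class SpatialRun:
    """Per-generation statistics of a chain simulation."""

    stats: pd.DataFrame
    final_chain: RepeatChain
    kymograph: list[str] | None = None
    extinct: bool = False

    @property
    def truncated(self) -> bool:
        return self.extinct


def run(
    chain0: RepeatChain,
    params: SpatialParameters,
    n_generations: int,
    *,
    seed: int | None = None,
    gap_tolerance: float = 0.2,
    record_kymograph: bool = False,
) -> SpatialRun:
    """Simulate ``n_generations`` and collect per-generation statistics.

    ``seed`` (if given) re-seeds the chain's stream before the run.  The
    run stops early if the chain goes extinct (copy number zero); the
    statistics frame then covers the generations actually simulated.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    chain = chain0
    if seed is not None:
        chain = RepeatChain(chain0.states.copy(), chain0.generation, seed)
    rows = []
    kymo: list[str] | None = [] if record_kymograph else None

    def record(ch: RepeatChain) -> None:
        cn, n_m = ch.copy_number, ch.n_methylated
        domains, mean_size = m_domains(ch, gap_tolerance)
        rows.append({
            "generation": ch.generation,
            "copy_number": cn,
            "n_methylated": n_m,
            "methylated_fraction": (n_m / cn) if cn else math.nan,
            "transcripts": ch.last_events.get("transcripts", math.nan),
            "insertions": ch.last_events.get("insertions", 0),
            "deletions": ch.last_events.get("deletions", 0),
            "mean_m_domain_size": mean_size,
            "n_m_domains": len(domains),
        })
        if kymo is not None:
            kymo.append(ch.to_rle())

    record(chain)
    extinct = chain.copy_number == 0
    for _ in range(n_generations):
        chain = step(chain, params)
        record(chain)
        if chain.extinct:
            extinct = True
            log.warning("chain went extinct at generation %d", chain.generation)
            break
    return SpatialRun(pd.DataFrame(rows), chain, kymo, extinct)


def m_domains(chain, gap_tolerance: float = 0.2) -> tuple[list[tuple[int, int, int]], float]:
    """Silenced domains: runs of M merged across gaps of up to 20 % U.

    Maximal M runs are merged left to right with the next run whenever the
    merged span keeps its U fraction at or below ``gap_tolerance``; the
    domain size is the merged span length (interior U included).  Returns
    ``(domains, mean_size)`` with domains as (start, end, size), end
    exclusive; ``mean_size`` is NaN when the chain holds no M.
    """
    if not 0.0 <= gap_tolerance < 1.0:
        raise ValueError("gap_tolerance must be in [0, 1)")
    s = chain.states if isinstance(chain, RepeatChain) else np.asarray(chain, dtype=bool)
    if s.size == 0 or not s.any():
        return [], math.nan
    # maximal runs of M as (start, end) half-open
    d = np.diff(s.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if s[0]:
        starts.insert(0, 0)
    if s[-1]:
        ends.append(s.size)

    domains: list[tuple[int, int, int]] = []
    cur_start, cur_end = starts[0], ends[0]
    cur_m = cur_end - cur_start
    for a, b in zip(starts[1:], ends[1:]):
        span = b - cur_start
        m = cur_m + (b - a)
        if (span - m) / span <= gap_tolerance:
            cur_end, cur_m = b, m
        else:
            domains.append((cur_start, cur_end, cur_end - cur_start))
            cur_start, cur_end, cur_m = a, b, b - a
    domains.append((cur_start, cur_end, cur_end - cur_start))
    mean_size = float(np.mean([d[2] for d in domains]))
    return domains, mean_size


def phase_grid(
    eta_range,
    phi_range,
    params: SpatialParameters = SpatialParameters(),
    *,
    replicates: int = 3,
    horizon: int = 200,
    seed: int = 0,
    chain_length: int = 1000,
    init_fraction: float = 0.5,
) -> pd.DataFrame:
    """Long-run methylated fraction over a (eta, phi) grid.

    For each cell the chain is simulated ``replicates`` times for
    ``horizon`` generations; the reported fraction is the mean over the
    final quarter of each run, averaged across replicates.  Extinctions
    are counted per cell, not hidden.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    eta_range = np.asarray(eta_range, dtype=float)
    phi_range = np.asarray(phi_range, dtype=float)
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(eta_range.size * phi_range.size * replicates))
    rows = []
    for e in eta_range:
        for f in phi_range:
            p = params.replace(eta=float(e), phi=float(f))
            fracs, n_ext = [], 0
            for _ in range(replicates):
                rep_seed = int(next(child).generate_state(1)[0] % (2 ** 31))
                chain = RepeatChain.random(chain_length, init_fraction, rep_seed)
                out = run(chain, p, horizon)
                if out.extinct:
                    n_ext += 1
                tail = out.stats["methylated_fraction"].iloc[-max(1, horizon // 4):]
                fracs.append(float(tail.mean()))
            rows.append({"eta": float(e), "phi": float(f),
                         "methylated_fraction": float(np.nanmean(fracs)),
                         "extinctions": n_ext})
    return pd.DataFrame(rows)


def mean_field_increments(
    n_methylated: float, copy_number: float, params: SpatialParameters
) -> tuple[float, float]:
    """Expected one-generation increments (dnM, dCN) under global cooperativity.

    With ``neighborhood_radius="global"`` every U is eligible whenever any
    M exists, so E[dnM] = (CN - nM) * p - mu * nM with
    p = 1 - (1-eta)(1-phi) (p = eta when nM = 0), and
    E[dCN] = sigma * n_transcript / (1 + nM/kappa3)
             - gamma * CN**2 / (1 + nM/kappa4),
    the transcript level being the quasi-steady RNA of the ODE model.  The
    dCN expression coincides exactly with the ODE copy-number equation
    under the QSSA; the dnM expression is the ODE methylation equation
    with its saturating cooperative term replaced by the eligibility form
    (and reduces to it when phi = 0).  Valid when the deletion cap is
    rarely hit (mean deletions << U count).
    """
    n_m, cn = float(n_methylated), float(copy_number)
    p = params.methylation_probability_eligible if n_m > 0 else params.eta
    d_nm = (cn - n_m) * p - params.mu * n_m
    ntr = transcript_level(n_m, cn, params)
    d_cn = params.sigma * ntr / (1.0 + n_m / params.kappa3) \
        - params.gamma * cn ** 2 / (1.0 + n_m / params.kappa4)
    return d_nm, d_cn


def ode_equivalent_parameters(params: SpatialParameters) -> ModelParameters:
    """ODE parameter set whose copy-number equation matches the chain's
    expected insertion/deletion balance (used for mean-field cross-checks).

    The mapping keeps alpha, delta, sigma, gamma and the repression scales;
    the chain's transcript repression scale ``kappa`` plays the role of the
    ODE's transcription scale ``kappa1``.  The methylation probabilities
    map onto eta and mu directly; phi and kappa2 have no exact ODE
    counterpart under local cooperativity and are passed through as-is.
    """
    return ModelParameters(
        alpha=params.alpha, delta=params.delta, phi=params.phi,
        eta=params.eta, mu=params.mu, sigma=params.sigma, gamma=params.gamma,
        kappa1=params.kappa, kappa2=params.kappa, kappa3=params.kappa3,
        kappa4=params.kappa4,
    )
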