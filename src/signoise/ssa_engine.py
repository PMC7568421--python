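"""Exact stochastic simulation (Gillespie direct method) of discrete reaction systems.

The engine works on integer molecule counts in a well-stirred, constant-volume,
constant-temperature compartment.  Reactions carry one of five kinds that fix
the propensity form:

* ``association``        -- ``k_a/(V*N_Avogadro) * N_a * N_b`` (bimolecular,
  rate constant in M^-1 s^-1; the volume factor converts it to count units)
* ``dissociation``, ``first-order-synthesis``, ``first-order-decay``
  -- ``k * N_reactant`` (rate constant in s^-1)
* ``conditional-synthesis`` -- ``k * indicator(N_reactant >= 1)`` (s^-1); used
  for transcription from a single regulated gene copy, which fires at a flat
  rate while its promoter site is occupied and not at all otherwise, thereby
  avoiding leaky expression.

The inner simulation loop is JIT-compiled with numba; the stepwise API
(:func:`propensities`, :func:`gillespie_step`) is plain numpy and is what the
test-suite oracles exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numba
import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "ABSORBED",
    "InvalidStateError",
    "Reaction",
    "ReactionSystem",
    "SimulationConfig",
    "EndpointSample",
    "propensities",
    "gillespie_step",
    "sample_endpoints",
]

#: Avogadro's number (mol^-1); fixed physical constant.
AVOGADRO = 6.02214076e23

#: Waiting time returned by :func:`gillespie_step` when no reaction can fire.
ABSORBED = math.inf

_KIND_CODES = {
    "association": 0,
    "dissociation": 1,
    "first-order-synthesis": 1,
    "first-order-decay": 1,
    "conditional-synthesis": 2,
}


class InvalidStateError(ValueError):
    """Raised when a state vector contains a negative molecule count."""


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction channel.

    Parameters
    ----------
    kind
        One of ``association``, ``dissociation``, ``conditional-synthesis``,
        ``first-order-synthesis``, ``first-order-decay``.
    rate_constant
        Macroscopic rate constant: M^-1 s^-1 for association, s^-1 otherwise.
    reactants
        Species names whose counts enter the propensity (two for association,
        exactly one for every first-order / conditional kind).
    change
        Mapping species name -> integer stoichiometric change applied when the
        reaction fires.
    """

    kind: str
    rate_constant: float
    reactants: tuple[str, ...]
    change: dict[str, int]
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.rate_constant < 0:
            raise ValueError("rate constant must be >= 0")
        n = len(self.reactants)
        if self.kind == "association" and n != 2:
            raise ValueError("association reactions need exactly two reactants")
        if self.kind != "association" and n != 1:
            raise ValueError(f"{self.kind} reactions need exactly one reactant")


@dataclass
class ReactionSystem:
    """A named reaction network with integer-count species.

    ``conserved`` lists linear invariants as ``(label, species-names, total)``;
    :meth:`check_state` verifies them and the non-negativity of a state.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    volume_liters: float
    conserved: tuple[tuple[str, tuple[str, ...], int], ...] = ()
    output_species: str = ""
    _compiled: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.volume_liters <= 0:
            raise ValueError("volume must be > 0")
        idx = {s: i for i, s in enumerate(self.species)}
        if len(idx) != len(self.species):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for s in (*r.reactants, *r.change):
                if s not in idx:
                    raise ValueError(f"reaction references unknown species {s!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def compiled(self) -> tuple:
        """Arrays (kinds, rates, r1, r2, change) for the jitted inner loop.

        Association rate constants are pre-divided by ``V * N_Avogadro`` so
        every compiled rate is in per-count units (s^-1 per reactant count).
        """
        if self._compiled is None:
            nr = len(self.reactions)
            kinds = np.empty(nr, dtype=np.int8)
            rates = np.empty(nr, dtype=np.float64)
            r1 = np.empty(nr, dtype=np.int64)
            r2 = np.full(nr, -1, dtype=np.int64)
            change = np.zeros((nr, self.n_species), dtype=np.int64)
            vna = self.volume_liters * AVOGADRO
            for j, r in enumerate(self.reactions):
                kinds[j] = _KIND_CODES[r.kind]
                rates[j] = r.rate_constant / vna if r.kind == "association" else r.rate_constant
                r1[j] = self.index(r.reactants[0])
                if len(r.reactants) == 2:
                    r2[j] = self.index(r.reactants[1])
                for s, d in r.change.items():
                    change[j, self.index(s)] = d
            self._compiled = (kinds, rates, r1, r2, change)
        return self._compiled

    def check_state(self, state: np.ndarray) -> None:
        """Raise if ``state`` is negative or violates a declared conserved sum."""
        state = np.asarray(state)
        if (state < 0).any():
            raise InvalidStateError(f"negative count in state {state}")
        for label, names, total in self.conserved:
            got = int(sum(state[self.index(s)] for s in names))
            if got != total:
                raise InvalidStateError(
                    f"conserved sum {label!r} is {got}, expected {total}"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling protocol: record the state at ``t_sample`` seconds, for
    ``replicates`` independent trajectories seeded from one master ``seed``."""

    t_sample: float
    seed: int
    replicates: int = 1000

    def __post_init__(self) -> None:
        if self.t_sample <= 0:
            raise ValueError("t_sample must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class EndpointSample:
    """Per-replicate species counts recorded at the sampling horizon."""

    species: tuple[str, ...]
    counts: np.ndarray  # shape (replicates, n_species), int64
    t_sample: float
    seed: int

    @property
    def replicates(self) -> int:
        return self.counts.shape[0]

    def counts_of(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "replicate", np.arange(self.replicates))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, t_sample: float = math.nan, seed: int = -1) -> "EndpointSample":
        df = pd.read_csv(path, sep="\t")
        species = tuple(c for c in df.columns if c != "replicate")
        counts = df[list(species)].to_numpy(dtype=np.int64)
        return cls(species=species, counts=counts, t_sample=t_sample, seed=seed)


def propensities(state: Sequence[int], system: ReactionSystem) -> np.ndarray:
    """Propensity (s^-1) of every reaction in the given state.

    Association channels evaluate ``k_a/(V*N_A) * N_a * N_b``, first-order
    channels ``k * N``, and conditional-synthesis channels fire at the flat
    rate ``k`` whenever the controlling complex count is at least one.
    """
    state = np.asarray(state, dtype=np.int64)
    if (state < 0).any():
        raise InvalidStateError(f"negative count in state {state}")
    kinds, rates, r1, r2, _ = system.compiled()
    a = np.empty(len(rates))
    for j in range(len(rates)):
        if kinds[j] == 0:
            a[j] = rates[j] * state[r1[j]] * state[r2[j]]
        elif kinds[j] == 1:
            a[j] = rates[j] * state[r1[j]]
        else:
            a[j] = rates[j] if state[r1[j]] >= 1 else 0.0
    return a


def gillespie_step(
    state: Sequence[int], system: ReactionSystem, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One event of the direct method.

    Returns ``(next_state, waiting_time)``.  The waiting time is exponential
    with rate equal to the total propensity and the fired channel is chosen
    with probability proportional to its propensity (cumulative sums in
    declared reaction order).  When every propensity is zero the state is
    absorbed: the unchanged state is returned with waiting time
    :data:`ABSORBED` (``inf``).
    """
    state = np.asarray(state, dtype=np.int64)
    a = propensities(state, system)
    a0 = a.sum()
    if a0 <= 0.0:
        return state.copy(), ABSORBED
    tau = rng.exponential(1.0 / a0)
    j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="left"))
    _, _, _, _, change = system.compiled()
    return state + change[j], tau


@numba.njit(cache=False)
def _endpoint_run(seed, state, kinds, rates, r1, r2, change, t_max):  # pragma: no cover - jitted
    np.random.seed(seed)
    nr = kinds.shape[0]
    ns = state.shape[0]
    a = np.empty(nr)
    t = 0.0
    while True:
        a0 = 0.0
        for j in range(nr):
            k = kinds[j]
            if k == 0:
                aj = rates[j] * state[r1[j]] * state[r2[j]]
            elif k == 1:
                aj = rates[j] * state[r1[j]]
            else:
                aj = rates[j] if state[r1[j]] >= 1 else 0.0
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            return  # absorbed: state frozen for all remaining time
        t += -math.log(np.random.random()) / a0
        if t >= t_max:
            return
        u = np.random.random() * a0
        acc = 0.0
        j = 0
        for jj in range(nr):
            acc += a[jj]
            j = jj
            if u <= acc:
                break
        for s in range(ns):
            state[s] += change[j, s]


def sample_endpoints(
    system: ReactionSystem,
    initial_state_factory: Callable[[np.random.Generator], Sequence[int]],
    config: SimulationConfig,
) -> EndpointSample:
    """Simulate ``config.replicates`` trajectories and record each state at
    ``config.t_sample``.

    The factory is re-invoked per replicate with a replicate-specific
    generator, so stochastic initial conditions (binomial promoter occupancy,
    negative-binomial polymerase copy number) are redrawn every time.  All
    randomness descends deterministically from the single master seed, so
    identical ``(system, factory, config)`` give bit-identical samples.
    """
    kinds, rates, r1, r2, change = system.compiled()
    out = np.empty((config.replicates, system.n_species), dtype=np.int64)
    master = np.random.SeedSequence(config.seed)
    for i, child in enumerate(master.spawn(config.replicates)):
        c_init, c_run = child.spawn(2)
        rng = np.random.Generator(np.random.PCG64(c_init))
        state = np.array(initial_state_factory(rng), dtype=np.int64)
        if (state < 0).any():
            raise InvalidStateError(f"factory produced negative counts {state}")
        run_seed = int(c_run.generate_state(1, dtype=np.uint32)[0])
        _endpoint_run(run_seed, state, kinds, rates, r1, r2, change, config.t_sample)
        out[i] = state
    return EndpointSample(
        species=system.species, counts=out, t_sample=config.t_sample, seed=config.seed
    )
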