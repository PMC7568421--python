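"""Closed-form results used to cross-validate the stochastic simulations.

The reversible binding of ``N_RT`` receptors and ``N_S`` signal molecules is a
birth-death chain on the complex count ``c = 0..min(N_RT, N_S)`` with

* birth rate ``lambda_c = k_d / Keq * (N_RT - c) (N_S - c)``  (association)
* death rate ``mu_c     = k_d * c``                            (dissociation)

(``Keq`` in count units).  Its stationary distribution follows from detailed
balance, ``pi_c / pi_0 = prod_{j=1..c} lambda_{j-1} / mu_j``, in which ``k_d``
cancels, so the equilibrium occupancy statistics depend on the affinity only
through ``Keq``.  The same chain solved brute-force through the null space of
its generator provides an independent numerical check.

For an always-on (constitutive) gene, the stationary protein mean and
standard deviation have the standard closed forms ``E(N_P) = (k1/d2)(k2/d1)``
and ``sd(N_P) = sqrt((k1/d2)(k2/d1)^2)``; a regulated gene at very strong
TF-DNA affinity must approach them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .info_metrics import MetricsTriple, ResponseEnsemble, metrics_triple

__all__ = [
    "StationaryDistribution",
    "binding_stationary_dist",
    "chain_stationary_nullspace",
    "exact_binding_metrics",
    "exact_binding_ensemble",
    "constitutive_moments",
]


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary occupancy distribution of the binding chain."""

    support: np.ndarray  # complex counts 0..min(N_RT, N_S)
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def mean(self) -> float:
        return float(self.support @ self.probabilities)

    @property
    def variance(self) -> float:
        return float((self.support - self.mean) ** 2 @ self.probabilities)


def binding_stationary_dist(
    n_receptors: int, n_signal: int, keq_count: float
) -> StationaryDistribution:
    """Detailed-balance stationary distribution of the complex count.

    ``keq_count`` is the equilibrium constant in count units (= molar value
    converted through the reaction volume); it must be positive.
    """
    if keq_count <= 0:
        raise ValueError("keq_count must be > 0")
    if min(n_receptors, n_signal) < 0:
        raise ValueError("counts must be >= 0")
    cmax = min(n_receptors, n_signal)
    log_pi = np.zeros(cmax + 1)
    for c in range(1, cmax + 1):
        lam = (n_receptors - c + 1) * (n_signal - c + 1) / keq_count
        log_pi[c] = log_pi[c - 1] + math.log(lam) - math.log(c)
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    return StationaryDistribution(np.arange(cmax + 1), pi)


def chain_stationary_nullspace(
    n_receptors: int, n_signal: int, keq_count: float
) -> StationaryDistribution:
    """Brute-force stationary vector of the full chain generator.

    Solves ``pi Q = 0`` with the normalization ``sum pi = 1`` as a dense
    linear system; independent of the detailed-balance construction and used
    as its oracle.
    """
    if keq_count <= 0:
        raise ValueError("keq_count must be > 0")
    cmax = min(n_receptors, n_signal)
    m = cmax + 1
    q = np.zeros((m, m))
    for c in range(m):
        if c < cmax:
            lam = (n_receptors - c) * (n_signal - c) / keq_count
            q[c, c + 1] = lam
            q[c, c] -= lam
        if c > 0:
            q[c, c - 1] = float(c)
            q[c, c] -= float(c)
    a = q.T.copy()
    a[-1, :] = 1.0  # replace one redundant balance row by normalization
    b = np.zeros(m)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return StationaryDistribution(np.arange(m), pi)


def exact_binding_ensemble(
    n_receptors: int, signal_levels: Sequence[int], keq_count: float
) -> ResponseEnsemble:
    """Exact response ensemble of the binding model (no sampling)."""
    levels = np.asarray(signal_levels, dtype=np.int64)
    if levels.size < 1:
        raise ValueError("need at least one signal level")
    support_max = min(n_receptors, int(levels.max()))
    support = np.arange(support_max + 1)
    pmf = np.zeros((levels.size, support.size))
    for i, ns in enumerate(levels):
        d = binding_stationary_dist(n_receptors, int(ns), keq_count)
        pmf[i, : d.support.size] = d.probabilities
    return ResponseEnsemble(levels, support, pmf, replicates_per_level=0)


def exact_binding_metrics(
    n_receptors: int, signal_levels: Sequence[int], keq_count: float
) -> MetricsTriple:
    """Information, noise and output range of the binding model computed
    exactly from the ``n`` stationary distributions."""
    return metrics_triple(exact_binding_ensemble(n_receptors, signal_levels, keq_count))


def constitutive_moments(
    k_transcription: float,
    k_translation: float,
    d_mrna: float,
    d_protein: float,
) -> tuple[float, float]:
    """Stationary protein mean and standard deviation of a constitutive gene.

    ``mean = (k1/d2)(k2/d1)`` and ``sd = sqrt((k1/d2)(k2/d1)^2)`` where
    ``k1``/``k2`` are the transcription/translation rates and ``d1``/``d2``
    the mRNA/protein decay rates.
    """
    if min(k_transcription, k_translation, d_mrna, d_protein) <= 0:
        raise ValueError("all rates must be > 0")
    mean = (k_transcription / d_protein) * (k_translation / d_mrna)
    sd = math.sqrt((k_transcription / d_protein) * (k_translation / d_mrna) ** 2)
    return mean, sd
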