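"""Summary statistics of response ensembles: mutual information, noise, range.

A :class:`ResponseEnsemble` holds, for each of ``n`` equiprobable signal
levels, the empirical probability mass function of the integer output count.
From it three quantities are computed:

* **information** ``I(S;O) = H(S) - H(S|O)`` in bits, with the plug-in
  estimator on the observed integer support (no binning, no bias
  correction; the replicate count is the bias control),
* **noise**, the Fano factor ``var/mean`` of the conditional response
  distribution averaged over the ``n`` levels,
* **output range**, the difference between the largest and smallest
  conditional mean response.

Conditional entropies are always evaluated through the joint distribution
``p(s, o) = p(o|s)/n`` rather than by re-normalizing sparse tables, which
avoids 0/0 at outputs never observed for some level.

Wide supports and estimator bias
--------------------------------
The plug-in estimator carries a positive undersampling bias that grows with
the number of occupied support values; for protein-count outputs (hundreds of
distinct values per level) the bias can exceed the signal of interest.
:func:`mutual_information` therefore coarsens any support wider than
``max_support`` (default 64) into that many equal-width bins before
estimating.  A *fixed* bin count keeps the residual bias comparable across
experimental conditions, and coarsening is a deterministic output map, so the
estimate still respects ``0 <= I <= log2 n``.  Small supports — e.g. complex
counts bounded by the receptor number — are never binned, and the noise and
output-range statistics always use the unbinned counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseEnsemble",
    "MetricsTriple",
    "shannon_entropy",
    "mutual_information",
    "average_fano",
    "output_range",
    "normalize_series",
    "metrics_triple",
    "bootstrap_information_se",
]

_PMF_TOL = 1e-9

#: Default maximum number of output values retained by the information
#: estimator; wider supports are merged into this many equal-width bins.
MAX_SUPPORT = 64


@dataclass(frozen=True)
class MetricsTriple:
    """Information (bits), noise (average Fano factor) and output range
    (counts) of one response ensemble."""

    information: float
    noise: float
    output_range: float


@dataclass
class ResponseEnsemble:
    """Per-signal-level empirical output distributions on a common support.

    ``pmf[i, j]`` is the probability of observing ``support[j]`` output
    molecules given signal level ``signal_levels[i]``; each row sums to one.
    """

    signal_levels: np.ndarray  # (n,)
    support: np.ndarray  # (m,) integer output counts
    pmf: np.ndarray  # (n, m)
    replicates_per_level: int

    def __post_init__(self) -> None:
        self.signal_levels = np.asarray(self.signal_levels)
        self.support = np.asarray(self.support, dtype=np.int64)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 2 or self.pmf.shape != (
            len(self.signal_levels),
            len(self.support),
        ):
            raise ValueError("pmf must be (n_levels, n_support)")
        if len(self.signal_levels) < 1:
            raise ValueError("need at least one signal level")
        if (self.support < 0).any():
            raise ValueError("output counts must be >= 0")
        if (self.pmf < 0).any() or np.abs(self.pmf.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("each conditional pmf must sum to 1")

    @property
    def n_levels(self) -> int:
        return len(self.signal_levels)

    @classmethod
    def from_samples(
        cls, signal_levels: Sequence[int], samples: Sequence[np.ndarray]
    ) -> "ResponseEnsemble":
        """Build the empirical ensemble from per-level replicate output counts."""
        if len(signal_levels) != len(samples) or len(samples) == 0:
            raise ValueError("need one sample array per signal level")
        reps = len(samples[0])
        support = np.unique(np.concatenate([np.asarray(s) for s in samples]))
        pmf = np.zeros((len(samples), len(support)))
        for i, s in enumerate(samples):
            s = np.asarray(s)
            if len(s) == 0:
                raise ValueError("empty sample array")
            idx = np.searchsorted(support, s)
            np.add.at(pmf[i], idx, 1.0 / len(s))
        return cls(np.asarray(signal_levels), support, pmf, reps)

    def coarsened(self, n_bins: int) -> "ResponseEnsemble":
        """Merge the output support into at most ``n_bins`` contiguous
        equal-width bins (a deterministic output mapping; by the
        data-processing inequality it can only lower mutual information).

        Bins are labeled by their (integer) lower edge.  Returns ``self``
        when the support is already small enough.
        """
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.support.size <= n_bins:
            return self
        lo, hi = int(self.support.min()), int(self.support.max())
        edges = np.linspace(lo, hi + 1, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, self.support, side="right") - 1, 0, n_bins - 1)
        pmf = np.zeros((self.n_levels, n_bins))
        for j, b in enumerate(idx):
            pmf[:, b] += self.pmf[:, j]
        labels = np.floor(edges[:-1]).astype(np.int64)
        keep = pmf.sum(axis=0) > 0
        return ResponseEnsemble(
            self.signal_levels, labels[keep], pmf[:, keep], self.replicates_per_level
        )

    def conditional_means(self) -> np.ndarray:
        return self.pmf @ self.support.astype(float)

    def conditional_vars(self) -> np.ndarray:
        mu = self.conditional_means()
        second = self.pmf @ (self.support.astype(float) ** 2)
        return np.maximum(second - mu**2, 0.0)

    # -- TSV round trip -------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = []
        for i, lev in enumerate(self.signal_levels):
            for j, o in enumerate(self.support):
                if self.pmf[i, j] > 0:
                    rows.append((lev, o, self.pmf[i, j], self.replicates_per_level))
        pd.DataFrame(
            rows, columns=["signal_level", "output_count", "probability", "replicates"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ResponseEnsemble":
        df = pd.read_csv(path, sep="\t")
        levels = np.array(sorted(df["signal_level"].unique()))
        support = np.array(sorted(df["output_count"].unique()), dtype=np.int64)
        li = {v: i for i, v in enumerate(levels)}
        oi = {v: j for j, v in enumerate(support)}
        pmf = np.zeros((len(levels), len(support)))
        for _, row in df.iterrows():
            pmf[li[row["signal_level"]], oi[row["output_count"]]] = row["probability"]
        return cls(levels, support, pmf, int(df["replicates"].iloc[0]))


def shannon_entropy(pmf: Sequence[float]) -> float:
    """Shannon entropy ``-sum p log2 p`` in bits, with ``0 log 0 := 0``."""
    p = np.asarray(pmf, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("pmf must be non-negative and sum to 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    ensemble: ResponseEnsemble, max_support: int | None = MAX_SUPPORT
) -> float:
    """Plug-in mutual information (bits) under the uniform signal prior.

    Evaluates ``sum_{s,o} p(s,o) log2[p(o|s)/p(o)]`` with the joint
    ``p(s,o) = p(o|s)/n``; the result lies in ``[0, log2 n]``.  Supports
    wider than ``max_support`` values are first merged into that many
    equal-width bins to control the undersampling bias of the plug-in
    estimate (pass ``max_support=None`` for the raw unbinned estimator).
    """
    if max_support is not None:
        ensemble = ensemble.coarsened(max_support)
    n = ensemble.n_levels
    joint = ensemble.pmf / n
    p_o = joint.sum(axis=0)
    mask = joint > 0
    ratio = np.where(mask, ensemble.pmf / np.where(p_o > 0, p_o, 1.0), 1.0)
    info = float((joint[mask] * np.log2(ratio[mask])).sum())
    return max(info, 0.0)


def average_fano(ensemble: ResponseEnsemble) -> float:
    """Noise: the Fano factor ``var/mean`` averaged over signal levels.

    A level whose conditional distribution is exactly the point mass at zero
    (mean 0, variance 0) contributes 0; a zero mean with non-zero variance is
    impossible for non-negative counts and raises.
    """
    mu = ensemble.conditional_means()
    var = ensemble.conditional_vars()
    terms = np.zeros_like(mu)
    pos = mu > 0
    terms[pos] = var[pos] / mu[pos]
    if ((~pos) & (var > 0)).any():
        raise ValueError("zero conditional mean with non-zero variance")
    return float(terms.mean())


def output_range(ensemble: ResponseEnsemble) -> float:
    """Difference between the largest and smallest conditional mean output."""
    mu = ensemble.conditional_means()
    return float(mu.max() - mu.min())


def metrics_triple(ensemble: ResponseEnsemble) -> MetricsTriple:
    return MetricsTriple(
        information=mutual_information(ensemble),
        noise=average_fano(ensemble),
        output_range=output_range(ensemble),
    )


def normalize_series(values: Sequence[float]) -> np.ndarray:
    """Divide a series by its maximum; an all-zero series maps to zeros."""
    v = np.asarray(values, dtype=float)
    m = v.max() if v.size else 0.0
    if m <= 0:
        return np.zeros_like(v)
    return v / m


def bootstrap_information_se(
    samples: Sequence[np.ndarray],
    signal_levels: Sequence[int],
    rng: np.random.Generator,
    n_boot: int = 100,
) -> float:
    """Bootstrap standard error of the plug-in mutual information.

    Replicate outputs are resampled with replacement within each signal level
    and the estimator recomputed ``n_boot`` times.
    """
    vals = np.empty(n_boot)
    samples = [np.asarray(s) for s in samples]
    for b in range(n_boot):
        res = [s[rng.integers(0, len(s), len(s))] for s in samples]
        vals[b] = mutual_information(ResponseEnsemble.from_samples(signal_levels, res))
    return float(vals.std(ddof=1))
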