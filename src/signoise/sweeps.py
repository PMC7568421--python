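"""Parameter-sweep orchestration: affinity sweeps, concentration-ratio and
dual-affinity grids, and the extrinsic-noise comparison.

Each sweep simulates a response ensemble per grid point (``replicates``
endpoint trajectories for each of the ``n`` signal levels), computes the
information / noise / output-range triple, and returns a
:class:`SweepResult` whose table carries both raw and max-normalized series.
All randomness descends from one master seed through per-point seed
sequences, so a sweep is bit-reproducible and its replicates are independent
(order of execution cannot change the result).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .info_metrics import (
    ResponseEnsemble,
    bootstrap_information_se,
    metrics_triple,
    normalize_series,
)
from .pathway_models import ModelSpec, build_model, initial_state
from .ssa_engine import SimulationConfig, sample_endpoints

__all__ = [
    "SweepResult",
    "response_ensemble",
    "affinity_sweep",
    "ratio_affinity_grid",
    "dual_affinity_grid",
    "extrinsic_noise_experiment",
    "find_optimum",
]

#: Biologically observed affinity windows (M) used only to warn when a sweep
#: leaves them: receptor-ligand binding and TF-DNA binding.
BIO_KEQ_RECEPTOR = (1e-9, 1e-6)
BIO_KEQ_TF_DNA = (1e-12, 1e-8)

_METRICS = ("information", "noise", "output_range")


@dataclass
class SweepResult:
    """Tabulated metrics over a parameter grid plus run provenance."""

    table: pd.DataFrame
    spec: ModelSpec
    seed: int
    replicates: int
    raw_samples: dict = field(default_factory=dict, repr=False)

    def to_tsv(self, path) -> None:
        buf = io.StringIO()
        buf.write(f"# variant: {self.spec.variant}\n")
        buf.write(f"# output: {self.spec.output_species}\n")
        buf.write(f"# seed: {self.seed}\n")
        buf.write(f"# replicates: {self.replicates}\n")
        buf.write(f"# t_sample_s: {self.spec.t_sample:g}\n")
        self.table.to_csv(buf, sep="\t", index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    def tsv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.table.to_csv(buf, sep="\t", index=False)
        return buf.getvalue().encode()


def _point_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0])


def response_ensemble(
    spec: ModelSpec, replicates: int, seed: int
) -> tuple[ResponseEnsemble, list[np.ndarray]]:
    """Simulate the response ensemble of ``spec`` over its signal grid.

    Returns the ensemble and the per-level raw output-count arrays (the
    latter feed bootstrap uncertainty estimates).
    """
    levels = spec.levels()
    master = np.random.SeedSequence(seed)
    samples: list[np.ndarray] = []
    for level_seq, ns in zip(master.spawn(len(levels)), levels):
        system = build_model(spec, int(ns))
        config = SimulationConfig(
            t_sample=spec.t_sample,
            seed=_point_seed(level_seq),
            replicates=replicates,
        )
        endpoints = sample_endpoints(
            system, lambda rng, _ns=int(ns): initial_state(spec, _ns, rng), config
        )
        samples.append(endpoints.counts_of(spec.output_species).copy())
    return ResponseEnsemble.from_samples(levels, samples), samples


def _warn_outside_bio_range(spec: ModelSpec, keq_grid_m: Sequence[float]) -> None:
    lo, hi = (
        BIO_KEQ_TF_DNA
        if spec.variant in ("gene", "gene_polymerase")
        else BIO_KEQ_RECEPTOR
    )
    outside = [k for k in keq_grid_m if not lo <= k <= hi]
    if outside:
        warnings.warn(
            f"K_eq values {outside} lie outside the biologically observed "
            f"window [{lo:g}, {hi:g}] M",
            stacklevel=3,
        )


def _attach_normalized(df: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    df = df.copy()
    for m in _METRICS:
        col = f"{m}_norm"
        if by:
            df[col] = df.groupby(list(by))[m].transform(
                lambda s: normalize_series(s.to_numpy())
            )
        else:
            df[col] = normalize_series(df[m].to_numpy())
    return df


def affinity_sweep(
    spec: ModelSpec,
    keq_grid_m: Sequence[float],
    replicates: int,
    seed: int,
    keep_raw: bool = False,
) -> SweepResult:
    """Sweep the (first) binding affinity over ``keq_grid_m`` (molar)."""
    keq_grid_m = sorted(keq_grid_m)
    _warn_outside_bio_range(spec, keq_grid_m)
    master = np.random.SeedSequence(seed)
    rows, raw = [], {}
    for point_seq, keq in zip(master.spawn(len(keq_grid_m)), keq_grid_m):
        point = spec.with_(keq_m=keq)
        ens, samples = response_ensemble(point, replicates, _point_seed(point_seq))
        t = metrics_triple(ens)
        rows.append(
            dict(keq_m=keq, information=t.information, noise=t.noise,
                 output_range=t.output_range)
        )
        if keep_raw:
            raw[keq] = samples
    df = _attach_normalized(pd.DataFrame(rows))
    return SweepResult(df, spec, seed, replicates, raw)


def ratio_affinity_grid(
    spec: ModelSpec,
    ratio_grid: Sequence[float],
    keq_grid_m: Sequence[float],
    replicates: int,
    seed: int,
) -> SweepResult:
    """Full factorial grid over receptor/signal ratio ``N_RT / N_Smax`` and
    affinity.  ``N_Smax`` is held at the template's value; each ratio sets
    ``N_RT = round(ratio * N_Smax)``.

    Cells where receptors outnumber signal molecules at the strongest grid
    affinity are flagged ``perfect_detection`` (the regime where the system
    simply counts its signal molecules and information is maximal without
    noise).
    """
    if len(ratio_grid) == 0 or len(keq_grid_m) == 0:
        raise ValueError("grids must be non-empty")
    ratio_grid = sorted(ratio_grid)
    keq_grid_m = sorted(keq_grid_m)
    strongest = min(keq_grid_m)
    master = np.random.SeedSequence(seed)
    seqs = iter(master.spawn(len(ratio_grid) * len(keq_grid_m)))
    rows = []
    for ratio in ratio_grid:
        n_rt = max(int(np.floor(ratio * spec.n_signal_max + 0.5)), 1)
        for keq in keq_grid_m:
            point = spec.with_(n_receptors=n_rt, keq_m=keq)
            ens, _ = response_ensemble(point, replicates, _point_seed(next(seqs)))
            t = metrics_triple(ens)
            rows.append(
                dict(
                    ratio=ratio,
                    n_receptors=n_rt,
                    keq_m=keq,
                    information=t.information,
                    noise=t.noise,
                    output_range=t.output_range,
                    perfect_detection=(spec.n_signal_max <= n_rt and keq == strongest),
                )
            )
    df = _attach_normalized(pd.DataFrame(rows))
    return SweepResult(df, spec, seed, replicates)


def dual_affinity_grid(
    spec: ModelSpec,
    keq_upstream_grid_m: Sequence[float],
    keq_downstream_grid_m: Sequence[float],
    replicates: int,
    seed: int,
) -> SweepResult:
    """Factorial grid over the receptor-signal affinity and the
    complex-DNA affinity of a consecutive-binding model (output RSD)."""
    if spec.variant not in ("cascade", "full_pathway"):
        raise ValueError("dual_affinity_grid needs a cascade or full_pathway spec")
    g1 = sorted(keq_upstream_grid_m)
    g2 = sorted(keq_downstream_grid_m)
    master = np.random.SeedSequence(seed)
    seqs = iter(master.spawn(len(g1) * len(g2)))
    rows = []
    for k1 in g1:
        for k2 in g2:
            point = spec.with_(keq_m=k1, keq_downstream_m=k2)
            ens, _ = response_ensemble(point, replicates, _point_seed(next(seqs)))
            t = metrics_triple(ens)
            rows.append(
                dict(keq_upstream_m=k1, keq_downstream_m=k2,
                     information=t.information, noise=t.noise,
                     output_range=t.output_range)
            )
    df = _attach_normalized(pd.DataFrame(rows))
    return SweepResult(df, spec, seed, replicates)


def extrinsic_noise_experiment(
    spec: ModelSpec,
    keq_grid_m: Sequence[float],
    sd_fractions: Sequence[float] = (0.0, 0.10, 0.30),
    replicates: int = 500,
    seed: int = 0,
    n_boot: int = 100,
) -> SweepResult:
    """Affinity sweeps of the polymerase gene model at several extrinsic-noise
    levels (polymerase copy number redrawn per replicate with the given
    coefficient of variation).

    The table carries one row per ``(sd_fraction, K_eq)`` with a bootstrap
    standard error on the information estimate; normalization is within each
    ``sd_fraction`` series.
    """
    if spec.variant != "gene_polymerase":
        raise ValueError("extrinsic_noise_experiment needs a gene_polymerase spec")
    master = np.random.SeedSequence(seed)
    sd_fractions = list(sd_fractions)
    rows = []
    for sd_seq, sd in zip(master.spawn(len(sd_fractions)), sd_fractions):
        sd_spec = spec.with_(polymerase_sd_fraction=sd)
        keqs = sorted(keq_grid_m)
        boot_seq, *point_seqs = sd_seq.spawn(len(keqs) + 1)
        boot_rng = np.random.Generator(np.random.PCG64(boot_seq))
        for point_seq, keq in zip(point_seqs, keqs):
            point = sd_spec.with_(keq_m=keq)
            ens, samples = response_ensemble(point, replicates, _point_seed(point_seq))
            t = metrics_triple(ens)
            se = bootstrap_information_se(samples, point.levels(), boot_rng, n_boot)
            rows.append(
                dict(sd_fraction=sd, keq_m=keq, information=t.information,
                     information_se=se, noise=t.noise, output_range=t.output_range)
            )
    df = _attach_normalized(pd.DataFrame(rows), by=("sd_fraction",))
    return SweepResult(df, spec, seed, replicates)


def max_information_by_sd(result: SweepResult) -> pd.DataFrame:
    """Per extrinsic-noise level: the affinity maximizing information, the
    information there, and its bootstrap standard error."""
    idx = result.table.groupby("sd_fraction")["information"].idxmax()
    cols = ["sd_fraction", "keq_m", "information", "information_se"]
    return result.table.loc[idx, cols].reset_index(drop=True)


def find_optimum(sweep: SweepResult) -> tuple[float, float, float]:
    """Grid point maximizing information in an affinity sweep.

    Returns ``(keq_m, information, normalized noise)`` at the optimum; exact
    information ties are broken toward the weaker affinity (larger K_eq).
    """
    df = sweep.table
    if len(df) < 2:
        raise ValueError("need at least two grid points")
    best = df[df["information"] == df["information"].max()]
    row = best.loc[best["keq_m"].idxmax()]
    return float(row["keq_m"]), float(row["information"]), float(row["noise_norm"])
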