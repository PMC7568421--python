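"""Construction of the five signaling-pathway reaction systems.

Variants
--------
``binding``
    Reversible receptor-signal association ``S + R <-> RS``; output ``RS``.
``cascade``
    Two consecutive reversible steps: ``S + R <-> RS`` and
    ``RS + D <-> RSD`` where ``D`` is a downstream DNA binding site;
    output ``RSD``.
``gene``
    A transcription factor reversibly occupies a promoter binding site;
    transcription fires only while the site is occupied; mRNA is translated
    into protein and both decay; output is the protein count ``P``.
``gene_polymerase``
    As ``gene``, but transcription additionally requires a polymerase
    molecule bound on top of the TF-occupied site (no leaky expression); the
    polymerase copy number is redrawn per replicate from a negative binomial
    distribution to model extrinsic noise.
``full_pathway``
    The complete linear chain: receptor-signal binding, complex-DNA binding,
    and gene expression driven by the occupied site; output ``P``.

Together with :mod:`signoise.ssa_engine` this module is the study's data
generator: there is no external data set, the simulator produces it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import defaults
from .ssa_engine import AVOGADRO, Reaction, ReactionSystem

__all__ = [
    "ModelSpec",
    "molar_to_count",
    "signal_grid",
    "expected_complexes",
    "build_model",
    "initial_state",
    "sample_polymerase_count",
]

VARIANTS = ("binding", "cascade", "gene", "gene_polymerase", "full_pathway")

_GENE_VARIANTS = ("gene", "gene_polymerase", "full_pathway")


def molar_to_count(concentration_m: float, volume_liters: float) -> float:
    """Convert a molar concentration to a (real-valued) molecule count.

    ``N = c * V * N_Avogadro``; the caller rounds where an integer count is
    required.
    """
    if concentration_m < 0:
        raise ValueError("concentration must be >= 0")
    if volume_liters <= 0:
        raise ValueError("volume must be > 0")
    return concentration_m * volume_liters * AVOGADRO


def signal_grid(n_signal_max: int, n_levels: int) -> np.ndarray:
    """The ``n`` signal counts, evenly spaced in ``[N_max/n, N_max]``.

    Values are ``i * N_max / n`` for ``i = 1..n`` rounded half-up to the
    nearest integer; with ``n <= N_max`` the spacing is at least one molecule,
    so the grid is strictly increasing.
    """
    if not 1 <= n_levels <= n_signal_max:
        raise ValueError(
            f"need 1 <= n_levels <= n_signal_max, got {n_levels} > {n_signal_max}"
        )
    raw = np.arange(1, n_levels + 1) * (n_signal_max / n_levels)
    return np.floor(raw + 0.5).astype(np.int64)


def expected_complexes(n_binding_total: int, n_signal: int, keq_count: float) -> float:
    """Expected complex count ``N_BT * N / (K_eq + N)`` at equilibrium.

    ``n_binding_total`` is the total receptor (or DNA-site) count and
    ``n_signal`` the signal/TF copy number; ``keq_count`` must already be in
    count units.  The value is clamped to ``n_signal`` so that the expected
    number of complexes never exceeds the molecules available to form them
    (relevant when receptors outnumber signal molecules at strong affinity).
    """
    if min(n_binding_total, n_signal, keq_count) < 0:
        raise ValueError("arguments must be >= 0")
    denom = keq_count + n_signal
    if denom == 0:
        return 0.0
    return min(n_binding_total * n_signal / denom, float(n_signal))


def sample_polymerase_count(
    mean: float, sd_fraction: float, rng: np.random.Generator
) -> int:
    """Draw a polymerase copy number.

    ``sd_fraction = 0`` returns ``round(mean)`` deterministically (no
    extrinsic noise).  Otherwise the draw is negative binomial with mean ``m``
    and standard deviation ``sd_fraction * m``, parameterized through
    ``p = m / var`` and ``r = m^2 / (var - m)``; this requires
    over-dispersion, ``var > m``.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be >= 0")
    if sd_fraction == 0:
        return int(math.floor(mean + 0.5))
    var = (sd_fraction * mean) ** 2
    if var <= mean:
        raise ValueError(
            "negative binomial requires variance > mean; "
            f"need sd_fraction > {1.0 / math.sqrt(mean):.4g} at mean {mean:g}"
        )
    r = mean * mean / (var - mean)
    p = mean / var
    return int(rng.negative_binomial(r, p))


@dataclass(frozen=True)
class ModelSpec:
    """Parameterization of one pathway variant.

    ``n_receptors`` is the total receptor count N_RT for binding variants and
    the number of promoter binding sites B (1..10) for gene variants.
    Concentration-like parameters (``keq_*``) are in molar and are converted
    to count units through ``volume_liters``; all rates are s^-1.
    """

    variant: str
    n_receptors: int
    n_signal_max: int
    n_levels: int
    keq_m: float
    volume_liters: float
    kd: float
    # second (complex-DNA) binding step: cascade / full_pathway
    keq_downstream_m: float | None = None
    kd_downstream: float | None = None
    n_sites: int = 1
    # gene expression
    k_transcription: float = defaults.K_TRANSCRIPTION
    k_translation: float = defaults.K_TRANSLATION
    d_mrna: float = defaults.D_MRNA
    d_protein: float = defaults.D_PROTEIN
    # polymerase / extrinsic noise
    keq_polymerase_m: float = defaults.KEQ_POLYMERASE_M
    kd_polymerase: float = defaults.KD_POLYMERASE
    polymerase_mean_multiplier: float = defaults.POLYMERASE_MEAN_MULTIPLIER
    polymerase_sd_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 1 <= self.n_levels <= self.n_signal_max:
            raise ValueError("need 1 <= n_levels <= n_signal_max")
        if self.keq_m <= 0 or self.volume_liters <= 0:
            raise ValueError("keq_m and volume must be > 0")
        for rate in (self.kd, self.k_transcription, self.k_translation,
                     self.d_mrna, self.d_protein, self.kd_polymerase):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.polymerase_sd_fraction < 0:
            raise ValueError("polymerase_sd_fraction must be >= 0")
        sites = self.binding_sites
        if self.variant in _GENE_VARIANTS or self.variant == "cascade":
            if not 1 <= sites <= 10:
                raise ValueError("number of DNA binding sites must lie in [1, 10]")

    # -- derived quantities ---------------------------------------------------

    @property
    def binding_sites(self) -> int:
        """Number of DNA binding sites B (gene variants use ``n_receptors``)."""
        if self.variant in ("gene", "gene_polymerase"):
            return self.n_receptors
        return self.n_sites

    @property
    def keq_count(self) -> float:
        return molar_to_count(self.keq_m, self.volume_liters)

    @property
    def keq_downstream_count(self) -> float | None:
        if self.keq_downstream_m is None:
            return None
        return molar_to_count(self.keq_downstream_m, self.volume_liters)

    @property
    def ka(self) -> float:
        """Association rate constant (M^-1 s^-1) implied by ``kd / keq``."""
        return self.kd / self.keq_m

    @property
    def output_species(self) -> str:
        return {"binding": "RS", "cascade": "RSD"}.get(self.variant, "P")

    @property
    def polymerase_mean(self) -> float:
        return self.polymerase_mean_multiplier * self.n_signal_max

    @property
    def t_sample(self) -> float:
        """Sampling horizon: >= 20 binding relaxation times for binding-only
        models, 10 slowest-decay lifetimes for gene-expression models."""
        if self.variant == "binding":
            return defaults.T_RELAX_BINDING / self.kd
        if self.variant == "cascade":
            return defaults.T_RELAX_BINDING / min(self.kd, self._kd2)
        return defaults.T_RELAX_GENE / min(self.d_mrna, self.d_protein)

    @property
    def _kd2(self) -> float:
        return self.kd_downstream if self.kd_downstream is not None else self.kd

    def levels(self) -> np.ndarray:
        return signal_grid(self.n_signal_max, self.n_levels)

    # -- canonical constructors ----------------------------------------------

    @classmethod
    def binding(cls, **over) -> "ModelSpec":
        base = dict(
            variant="binding",
            n_receptors=defaults.N_RECEPTORS,
            n_signal_max=defaults.N_SIGNAL_MAX,
            n_levels=defaults.N_LEVELS,
            keq_m=defaults.KEQ_RECEPTOR_SIGNAL_M,
            volume_liters=defaults.VOLUME_RECEPTOR_L,
            kd=defaults.KD_RECEPTOR_SIGNAL,
        )
        base.update(over)
        return cls(**base)

    @classmethod
    def cascade(cls, **over) -> "ModelSpec":
        base = dict(
            variant="cascade",
            n_receptors=defaults.N_RECEPTORS,
            n_signal_max=defaults.N_SIGNAL_MAX,
            n_levels=defaults.N_LEVELS,
            keq_m=defaults.KEQ_RECEPTOR_SIGNAL_M,
            volume_liters=defaults.VOLUME_RECEPTOR_L,
            kd=defaults.KD_RECEPTOR_SIGNAL,
            keq_downstream_m=defaults.KEQ_COMPLEX_DNA_M,
            kd_downstream=defaults.KD_TF_DNA,
            n_sites=1,
        )
        base.update(over)
        return cls(**base)

    @classmethod
    def gene(cls, **over) -> "ModelSpec":
        base = dict(
            variant="gene",
            n_receptors=1,  # one promoter binding site
            n_signal_max=defaults.N_TF_MAX,
            n_levels=defaults.N_LEVELS,
            keq_m=defaults.KEQ_TF_DNA_M,
            volume_liters=defaults.VOLUME_NUCLEUS_L,
            kd=defaults.KD_TF_DNA,
        )
        base.update(over)
        return cls(**base)

    @classmethod
    def gene_polymerase(cls, **over) -> "ModelSpec":
        base = dict(variant="gene_polymerase")
        merged = cls.gene().__dict__ | base | over
        return cls(**merged)

    @classmethod
    def full_pathway(cls, **over) -> "ModelSpec":
        base = dict(
            variant="full_pathway",
            n_receptors=defaults.N_RECEPTORS,
            n_signal_max=defaults.N_SIGNAL_MAX,
            n_levels=defaults.N_LEVELS,
            keq_m=defaults.KEQ_RECEPTOR_SIGNAL_M,
            volume_liters=defaults.VOLUME_RECEPTOR_L,
            kd=defaults.KD_RECEPTOR_SIGNAL,
            keq_downstream_m=1e-8,
            kd_downstream=defaults.KD_TF_DNA,
            n_sites=1,
        )
        base.update(over)
        return cls(**base)

    def with_(self, **over) -> "ModelSpec":
        return replace(self, **over)


# ---------------------------------------------------------------------------
# reaction-system construction
# ---------------------------------------------------------------------------


def _gene_expression_reactions(promoter_species: str, single_site: bool,
                               spec: ModelSpec) -> list[Reaction]:
    """Transcription/translation/decay block driven by an occupied promoter.

    For a single gene copy transcription is conditional: flat rate ``k_1``
    while the site is occupied, zero otherwise.  With several independent site
    copies each occupied site contributes ``k_1``.
    """
    tx_kind = "conditional-synthesis" if single_site else "first-order-synthesis"
    return [
        Reaction(tx_kind, spec.k_transcription, (promoter_species,),
                 {"mR": +1}, name="transcription"),
        Reaction("first-order-decay", spec.d_mrna, ("mR",), {"mR": -1},
                 name="mRNA decay"),
        Reaction("first-order-synthesis", spec.k_translation, ("mR",),
                 {"P": +1}, name="translation"),
        Reaction("first-order-decay", spec.d_protein, ("P",), {"P": -1},
                 name="protein decay"),
    ]


def build_model(spec: ModelSpec, n_signal: int) -> ReactionSystem:
    """Assemble the reaction system for ``spec`` at one signal level.

    ``n_signal`` is the total signal (or TF) copy number N_S for this level;
    conserved sums for the receptor and signal totals are declared on the
    returned system.
    """
    if n_signal < 1:
        raise ValueError("n_signal must be >= 1")
    ka = spec.ka
    b = spec.binding_sites

    if spec.variant == "binding":
        species = ("S", "R", "RS")
        reactions = (
            Reaction("association", ka, ("S", "R"),
                     {"S": -1, "R": -1, "RS": +1}, name="S+R association"),
            Reaction("dissociation", spec.kd, ("RS",),
                     {"S": +1, "R": +1, "RS": -1}, name="RS dissociation"),
        )
        conserved = (
            ("total receptors", ("R", "RS"), spec.n_receptors),
            ("total signal", ("S", "RS"), n_signal),
        )
        return ReactionSystem(species, reactions, spec.volume_liters,
                              conserved, output_species="RS")

    if spec.variant == "cascade":
        ka2 = spec._kd2 / spec.keq_downstream_m
        species = ("S", "R", "RS", "D", "RSD")
        reactions = (
            Reaction("association", ka, ("S", "R"),
                     {"S": -1, "R": -1, "RS": +1}, name="S+R association"),
            Reaction("dissociation", spec.kd, ("RS",),
                     {"S": +1, "R": +1, "RS": -1}, name="RS dissociation"),
            Reaction("association", ka2, ("RS", "D"),
                     {"RS": -1, "D": -1, "RSD": +1}, name="RS+D association"),
            Reaction("dissociation", spec._kd2, ("RSD",),
                     {"RS": +1, "D": +1, "RSD": -1}, name="RSD dissociation"),
        )
        conserved = (
            ("total receptors", ("R", "RS", "RSD"), spec.n_receptors),
            ("total signal", ("S", "RS", "RSD"), n_signal),
            ("total DNA sites", ("D", "RSD"), b),
        )
        return ReactionSystem(species, reactions, spec.volume_liters,
                              conserved, output_species="RSD")

    if spec.variant == "gene":
        species = ("TF", "Dbs", "TFD", "mR", "P")
        reactions = (
            Reaction("association", ka, ("TF", "Dbs"),
                     {"TF": -1, "Dbs": -1, "TFD": +1}, name="TF+DNA association"),
            Reaction("dissociation", spec.kd, ("TFD",),
                     {"TF": +1, "Dbs": +1, "TFD": -1}, name="TF-DNA dissociation"),
            *_gene_expression_reactions("TFD", b == 1, spec),
        )
        conserved = (
            ("total TF", ("TF", "TFD"), n_signal),
            ("total DNA sites", ("Dbs", "TFD"), b),
        )
        return ReactionSystem(species, reactions, spec.volume_liters,
                              conserved, output_species="P")

    if spec.variant == "gene_polymerase":
        ka_pol = spec.kd_polymerase / spec.keq_polymerase_m
        species = ("TF", "Dbs", "TFD", "Pol", "TFPD", "mR", "P")
        reactions = (
            Reaction("association", ka, ("TF", "Dbs"),
                     {"TF": -1, "Dbs": -1, "TFD": +1}, name="TF+DNA association"),
            Reaction("dissociation", spec.kd, ("TFD",),
                     {"TF": +1, "Dbs": +1, "TFD": -1}, name="TF-DNA dissociation"),
            # polymerase can only bind a TF-occupied site
            Reaction("association", ka_pol, ("Pol", "TFD"),
                     {"Pol": -1, "TFD": -1, "TFPD": +1}, name="Pol+TFD association"),
            Reaction("dissociation", spec.kd_polymerase, ("TFPD",),
                     {"Pol": +1, "TFD": +1, "TFPD": -1}, name="Pol unbinding"),
            # TF unbinding evicts the polymerase as well
            Reaction("dissociation", spec.kd, ("TFPD",),
                     {"TF": +1, "Dbs": +1, "Pol": +1, "TFPD": -1},
                     name="TF unbinding with Pol eviction"),
            *_gene_expression_reactions("TFPD", b == 1, spec),
        )
        conserved = (
            ("total TF", ("TF", "TFD", "TFPD"), n_signal),
            ("total DNA sites", ("Dbs", "TFD", "TFPD"), b),
        )
        return ReactionSystem(species, reactions, spec.volume_liters,
                              conserved, output_species="P")

    if spec.variant == "full_pathway":
        ka2 = spec._kd2 / spec.keq_downstream_m
        species = ("S", "R", "RS", "D", "RSD", "mR", "P")
        reactions = (
            Reaction("association", ka, ("S", "R"),
                     {"S": -1, "R": -1, "RS": +1}, name="S+R association"),
            Reaction("dissociation", spec.kd, ("RS",),
                     {"S": +1, "R": +1, "RS": -1}, name="RS dissociation"),
            Reaction("association", ka2, ("RS", "D"),
                     {"RS": -1, "D": -1, "RSD": +1}, name="RS+D association"),
            Reaction("dissociation", spec._kd2, ("RSD",),
                     {"RS": +1, "D": +1, "RSD": -1}, name="RSD dissociation"),
            *_gene_expression_reactions("RSD", b == 1, spec),
        )
        conserved = (
            ("total receptors", ("R", "RS", "RSD"), spec.n_receptors),
            ("total signal", ("S", "RS", "RSD"), n_signal),
            ("total DNA sites", ("D", "RSD"), b),
        )
        return ReactionSystem(species, reactions, spec.volume_liters,
                              conserved, output_species="P")

    raise ValueError(f"unknown variant {spec.variant!r}")


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _bernoulli_sites(n_sites: int, p_each: float, rng: np.random.Generator) -> int:
    return int(rng.binomial(n_sites, min(max(p_each, 0.0), 1.0)))


def initial_state(
    spec: ModelSpec, n_signal: int, rng: np.random.Generator
) -> np.ndarray:
    """Near-equilibrium initial counts for ``build_model(spec, n_signal)``.

    Receptor-signal complexes start at the nearest integer to the expected
    complex number; DNA-site occupancy is drawn Bernoulli with the expected
    occupancy probability per site.  mRNA and protein start at the rounded
    constitutive expectations scaled by the site-occupancy probability,
    ``N_mR = Nc * k1/d1`` and ``N_P = Nc * (k1/d1)(k2/d2)``.  Free-molecule
    counts are the totals minus the complexed counts, hence never negative.
    """
    keq = spec.keq_count
    b = spec.binding_sites

    if spec.variant == "binding":
        nc = _round_half_up(expected_complexes(spec.n_receptors, n_signal, keq))
        return np.array([n_signal - nc, spec.n_receptors - nc, nc], dtype=np.int64)

    if spec.variant == "cascade":
        nc = _round_half_up(expected_complexes(spec.n_receptors, n_signal, keq))
        # downstream site occupancy from the expected free-complex count
        p_site = 0.0
        if nc > 0:
            p_site = expected_complexes(1, nc, spec.keq_downstream_count)
        n_rsd = _bernoulli_sites(b, p_site, rng)
        n_rsd = min(n_rsd, nc)
        return np.array(
            [n_signal - nc, spec.n_receptors - nc, nc - n_rsd, b - n_rsd, n_rsd],
            dtype=np.int64,
        )

    if spec.variant in ("gene", "gene_polymerase"):
        p_occ = expected_complexes(1, n_signal, keq)  # per-site occupancy prob.
        n_occ = _bernoulli_sites(b, p_occ, rng)
        n_occ = min(n_occ, n_signal)
        nc_hat = b * p_occ
        n_mr = _round_half_up(nc_hat * spec.k_transcription / spec.d_mrna)
        n_p = _round_half_up(
            nc_hat * (spec.k_transcription / spec.d_mrna)
            * (spec.k_translation / spec.d_protein)
        )
        if spec.variant == "gene":
            return np.array(
                [n_signal - n_occ, b - n_occ, n_occ, n_mr, n_p], dtype=np.int64
            )
        n_pol = sample_polymerase_count(
            spec.polymerase_mean, spec.polymerase_sd_fraction, rng
        )
        # polymerase starts unbound; it equilibrates on the ~1/kd_polymerase
        # timescale, far faster than the protein lifetime
        return np.array(
            [n_signal - n_occ, b - n_occ, n_occ, n_pol, 0, n_mr, n_p],
            dtype=np.int64,
        )

    if spec.variant == "full_pathway":
        nc = _round_half_up(expected_complexes(spec.n_receptors, n_signal, keq))
        p_site = 0.0
        if nc > 0:
            p_site = expected_complexes(1, nc, spec.keq_downstream_count)
        n_rsd = _bernoulli_sites(b, p_site, rng)
        n_rsd = min(n_rsd, nc)
        nc_hat = b * p_site
        n_mr = _round_half_up(nc_hat * spec.k_transcription / spec.d_mrna)
        n_p = _round_half_up(
            nc_hat * (spec.k_transcription / spec.d_mrna)
            * (spec.k_translation / spec.d_protein)
        )
        return np.array(
            [n_signal - nc, spec.n_receptors - nc, nc - n_rsd, b - n_rsd,
             n_rsd, n_mr, n_p],
            dtype=np.int64,
        )

    raise ValueError(f"unknown variant {spec.variant!r}")
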