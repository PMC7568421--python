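"""Default parameter values for the five pathway models.

Every default lives here (never hard-coded in model-building logic) and is
chosen from biologically sensible ranges: receptor-ligand affinities in the
micromolar-to-nanomolar window, TF-DNA affinities down to picomolar, mRNA
half-lives of minutes, protein half-lives of tens of minutes, TF residence
times on DNA of seconds to hours, and molecular concentrations between 1 nM
and 1 uM.  Units are listed per constant.
"""

import math

from .ssa_engine import AVOGADRO

# --- unit convention ---------------------------------------------------------
#: Reaction volume (L) for receptor-ligand models, chosen so that
#: V * N_Avogadro = 1e9 M^-1, i.e. 1 nM <-> 1 molecule (~1.66 fL, a bacterial
#: cytoplasm scale).  10 nM of receptor is then exactly 10 molecules.
VOLUME_RECEPTOR_L = 1e9 / AVOGADRO

#: Reaction volume (L) for gene-regulation models, chosen so that
#: V * N_Avogadro = 1e12 M^-1, i.e. 1 pM <-> 1 molecule (~1.66 pL, a
#: eukaryotic nucleus scale).  Picomolar TF-DNA affinities then correspond to
#: single-digit molecule counts, the regime where promoter occupancy actually
#: varies with TF copy number.
VOLUME_NUCLEUS_L = 1e12 / AVOGADRO

# --- binding steps -----------------------------------------------------------
#: Receptor-signal dissociation rate (s^-1).  Affinity sweeps vary
#: K_eq = k_d / k_a at fixed k_d, so this only sets the relaxation time.
KD_RECEPTOR_SIGNAL = 0.01

#: Complex-DNA / TF-DNA dissociation rate (s^-1); residence time 1000 s,
#: within the seconds-to-hours window measured for TFs on DNA.
KD_TF_DNA = 1e-3

#: Default receptor-signal equilibrium constant (M), mid-range of the
#: micromolar-to-nanomolar interval typical of ligand-receptor pairs.
KEQ_RECEPTOR_SIGNAL_M = 1e-7

#: Default complex-DNA equilibrium constant (M) for cascade / full-pathway
#: models (1 molecule at the receptor-model volume).
KEQ_COMPLEX_DNA_M = 1e-9

#: Default TF-DNA equilibrium constant (M) for gene-expression models.
KEQ_TF_DNA_M = 1e-11

# --- gene expression ---------------------------------------------------------
#: Transcription rate while the promoter is active (s^-1).
K_TRANSCRIPTION = 0.02
#: Translation rate per mRNA molecule (s^-1); k_2/k_1 = 2.5 > 1.
K_TRANSLATION = 0.05
#: mRNA decay rate (s^-1): half-life 2 min.
D_MRNA = math.log(2) / 120.0
#: Protein decay rate (s^-1): half-life 30 min.
D_PROTEIN = math.log(2) / 1800.0

# --- polymerase (extrinsic noise) -------------------------------------------
#: Polymerase-DNA equilibrium constant (M), a realistic promoter affinity.
KEQ_POLYMERASE_M = 1e-9
#: Polymerase unbinding rate from the TF-bound promoter (s^-1).
KD_POLYMERASE = 0.01
#: Mean polymerase copy number as a multiple of the maximal TF count.
POLYMERASE_MEAN_MULTIPLIER = 10.0

# --- study geometry ----------------------------------------------------------
#: Total receptors in the receptor-signal system: 10 nM = 10 molecules.
N_RECEPTORS = 10
#: Maximal signal count for receptor models: 1 uM = 1000 molecules.
N_SIGNAL_MAX = 1000
#: Maximal TF count for gene models: 100 pM = 100 molecules at the nucleus
#: volume, bracketing the default TF-DNA affinity grid.
N_TF_MAX = 100
#: Number of equiprobable signal levels.
N_LEVELS = 10
#: Replicate trajectories per signal level.
REPLICATES = 1000

#: Sampling-horizon multipliers (in units of the slowest relaxation time):
#: binding-only models are recorded at 20 / min(k_d), gene-expression models
#: at 10 / min(d_mrna, d_protein).  Initial states are placed at the expected
#: equilibrium, so these horizons yield effectively stationary draws.
T_RELAX_BINDING = 20.0
T_RELAX_GENE = 10.0
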