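# Methods

## Models and assumptions

All five model variants are networks of elementary reactions over integer
molecule counts in a well-stirred compartment of constant volume and
temperature. Dynamics are simulated exactly with Gillespie's direct method:
waiting times are exponential in the total propensity and the firing channel
is chosen with probability proportional to its propensity, using cumulative
sums in declared reaction order. Propensities follow mass action,

* association: `p_a = k_a/(V·N_A) · N_a · N_b` (k_a in M⁻¹s⁻¹; the
  `V·N_A` factor converts the macroscopic constant to count units),
* dissociation and all other first-order channels: `p = k · N`,
* transcription from a single gene copy: flat rate `k₁` while the promoter
  complex exists and 0 otherwise — expression is never leaky. With `B > 1`
  independent site copies each occupied site contributes `k₁`.

States with zero total propensity are absorbing: the state is recorded for
all remaining time, never treated as an error.

Totals are conserved by construction (free receptor + complexes = `N_RT`,
free signal + complexes = `N_S`, free sites + occupied sites = `B`), and
every constructed system declares these sums so a simulation endpoint can be
audited exactly.

## Units, volumes, copy numbers

Concentrations convert to counts as `N = c · V · N_A`. Two default volumes
are used, both configurable:

* receptor–ligand models: `V = 10⁹/N_A` L ≈ 1.66 fL (bacterial cytoplasm
  scale), so 1 nM ↔ 1 molecule. Defaults: `N_RT = 10` (10 nM receptor),
  signal up to `N_Smax = 1000` (1 µM) — signal in excess of receptors, the
  biologically typical arrangement.
* gene-regulation models: `V = 10¹²/N_A` L ≈ 1.66 pL (eukaryotic nucleus
  scale), so 1 pM ↔ 1 molecule. This makes picomolar TF–DNA affinities
  count-resolvable: `K_eq = 10⁻¹¹ M` ↔ 10 molecules, comparable to the
  default TF range `N_TFmax = 100` (10⁻¹⁰ M). With a femtoliter volume the
  entire empirical TF–DNA affinity window would collapse below one molecule
  and promoter occupancy would be saturated at every TF level, leaving no
  regime structure to study. `N_TFmax = 100` is our choice (hundreds to
  thousands of TF copies per nucleus are typical); it places the default
  affinity sweep `[10⁻⁹, 10⁻¹³] M` symmetrically around the intermediate
  regime, where `K_eq` falls inside the swept TF-concentration interval.

## Rate-constant defaults

Affinity sweeps vary `K_eq = k_d/k_a` with `k_d` held fixed and
`k_a = k_d/K_eq`; equilibrium occupancy statistics depend only on `K_eq`
(the closed-form stationary law is `k_d`-free), so this split affects
relaxation times only. Defaults, all overridable and all inside empirically
observed windows:

| constant | default | rationale |
| --- | --- | --- |
| `k_d` (receptor–signal) | 0.01 s⁻¹ | ~100 s complex lifetime |
| `k_d` (TF/complex–DNA) | 10⁻³ s⁻¹ | 1000 s residence, within the seconds-to-hours range for TFs on DNA |
| `k₁` (transcription) | 0.02 s⁻¹ | ~1 mRNA per min from an active promoter |
| `k₂` (translation) | 0.05 s⁻¹ | `k₂/k₁ = 2.5 > 1` |
| `d₁` (mRNA decay) | ln2/120 s⁻¹ | 2 min half-life (minutes-scale mRNA turnover) |
| `d₂` (protein decay) | ln2/1800 s⁻¹ | 30 min half-life |
| polymerase `K_eq` | 10⁻⁹ M | realistic promoter affinity |
| polymerase `k_d` | 0.01 s⁻¹ | fast (100 s) polymerase exchange, well inside the protein lifetime so occupancy averages out within a replicate |
| polymerase mean copies | 10 × `N_TFmax` | polymerases greatly outnumber TFs |

These gene-expression defaults give a constitutive protein mean of
`(k₁/d₂)(k₂/d₁) ≈ 450` molecules. We deliberately chose half-lives at the
fast end of their plausible windows: the qualitative relationships under
study depend on promoter-occupancy statistics, not on the absolute protein
scale, and a ~450-copy stationary state keeps a replicate at ~10⁴ events so
that full sweeps run on one CPU in seconds to tens of seconds. Problem sizes
used by the shipped analyses: 8–10 signal levels, 500–2000 replicates per
level, affinity grids of 5–9 points.

## Sampling protocol

The response to a signal level is the state at a fixed horizon `t_sample`:
20 relaxation times (`20/min(k_d)`) for binding-only models and 10 slowest
lifetimes (`10/min(d₁, d₂)`) for gene-expression models. Initial conditions
are placed at the expected equilibrium so endpoints approximate stationary
draws: complexes start at the nearest integer to
`N̂_C = N_BT·N_S/(K_eq + N_S)` for receptor–signal pairs and Bernoulli(`N̂_C`)
per DNA site (for which `N̂_C` is an occupancy probability); mRNA and protein
start at the rounded occupancy-weighted constitutive expectations
`N̂_C·k₁/d₁` and `N̂_C·(k₁/d₁)(k₂/d₂)`. `N̂_C` is clamped to the available
signal molecules so no initial count can be negative (the clamp matters only
when receptors outnumber signal at strong affinity). The endpoint histogram
at 2000 replicates is required (and tested) to sit within total-variation
distance 0.05 of the closed-form stationary law.

Randomness: one master seed per run; per-replicate child streams are derived
through numpy `SeedSequence` spawning (one stream for stochastic initial
conditions, one for the event loop), so runs are bit-reproducible and
replicates are order-independent.

## Metrics and estimators

The signal prior is uniform over the `n` grid levels
(`H(S) = log₂ n`); levels are `i·N_Smax/n`, `i = 1..n`, rounded half-up —
strictly increasing whenever `n ≤ N_Smax`.

* **Mutual information** is the plug-in estimate computed through the joint
  `p(s,o) = p(o|s)/n` (never by re-normalizing sparse conditional tables).
  Supports wider than 64 distinct output values are first merged into 64
  equal-width bins: the plug-in estimator's positive undersampling bias
  grows with the number of occupied support values, and for protein-count
  outputs (hundreds of distinct values at 500–1000 replicates) the
  uncorrected bias is larger than the effects under study and even inverts
  orderings between conditions. A fixed bin count keeps the residual bias
  comparable across the conditions being compared; coarsening is a
  deterministic output map, so `0 ≤ I ≤ log₂ n` still holds, and small
  supports (complex counts bounded by the receptor number) are never binned.
  Uncertainty on `I` is estimated by bootstrap resampling of replicates
  within each signal level.
* **Noise** is the average conditional Fano factor. A level whose response
  is exactly the point mass at zero contributes 0 (no fluctuation carries no
  noise); a zero mean with positive variance is impossible for counts and
  raises.
* **Output range** is the max−min of conditional mean responses; means and
  variances always use the unbinned counts.
* Normalized series divide by the series maximum; an all-zero series maps to
  zeros. The sweep optimum is the information argmax, with exact ties broken
  toward weaker affinity (larger `K_eq`). Localizing the optimum and the
  noise level there requires a grid finer than one point per decade: on the
  decade grid the flanking points straddle the true optimum with near-tied
  information, so the half-decade (9-point) sweep is used whenever the
  optimum's position or the noise fraction at the optimum is the quantity of
  interest.

## What the generator does and does not emulate

The simulator *is* the data source — there is no external data set. It
emulates intrinsic stochasticity of discrete binding, transcription and
translation events exactly (to the chemical master equation), and extrinsic
noise as replicate-to-replicate polymerase copy-number variation (negative
binomial, mean `10·N_TFmax`, coefficient of variation 0, 10 % or 30 %;
CV = 0 is deterministic and CVs below the over-dispersion limit
`1/√mean` are rejected). It does not emulate: cell growth or division,
time-varying signals or rate constants, spatial structure, cooperative
binding or dimerization, feedback loops, or costs of expressing the
machinery. Passing tests therefore demonstrate properties of the stationary
stochastic kinetics of these idealized motifs, not predictions for any
particular organism.

## Numerical and design notes

* The closed-form stationary law of the binding chain is computed in log
  space from the detailed-balance products and validated (to 10⁻¹⁰) against
  an independent dense null-space solve of the full generator for every
  `N_RT, N_S ≤ 12`; the oracle is authoritative — simulation must converge
  to it, never the reverse.
* Multiple DNA binding sites are modeled as one site-species with capacity
  `B` (equivalent to `B` independent identical sites); the cascade output is
  the total occupied-site count.
* In the consecutive-binding (cascade) model with one binary site, absolute
  information is necessarily small (`H(O) ≤ 1` bit) and its maximum over a
  dual-affinity grid sits where the site's occupancy spans the widest range
  — which includes weak-upstream/strong-downstream combinations, since weak
  upstream binding keeps the mean complex count linear in the signal. The
  saturated edges (either step permanently bound, or upstream saturated)
  reliably destroy the signal and are what the tests pin down.
* At this problem scale the extrinsic-noise degradation of information is
  small relative to Monte-Carlo error for the 10 % condition; the
  experiment therefore reports bootstrap standard errors and the monotone
  comparison is made within two pooled standard errors.

## Known limitations

Endpoint sampling reads one time point per replicate; time-averaged readouts
or trajectory-level information measures are out of scope. The plug-in
information estimate, binned or not, remains a biased estimator at finite
replicates — comparisons across conditions with matched replicate counts and
bin counts are meaningful, absolute bit values carry a small positive offset.
Tau-leaping/ODE approximations, spatial models, and channel-capacity
optimization over non-uniform signal priors are deliberately not provided.
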