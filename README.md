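# signoise

Exact stochastic simulation of reversible-binding signaling systems, and
information-theoretic analysis of how binding affinity shapes what a cell can
learn about its environment.

Cells detect signals through reversible molecular binding — a ligand to a
receptor, a transcription factor (TF) to a DNA site. `signoise` simulates five
variants of this motif with Gillespie's stochastic simulation algorithm and
quantifies, for each parameter setting, three properties of the response:

* **information** — the mutual information `I(S;O) = H(S) − H(S|O)` (bits)
  between the signal copy number `S` (uniform over `n` levels) and the output
  copy number `O`,
* **noise** — the Fano factor `σ²/μ` of the conditional response
  distribution `Pr(O | S)`, averaged over the `n` signal levels,
* **output range** — the spread `max_s μ(O|s) − min_s μ(O|s)` of the
  conditional mean responses.

The central result these tools reproduce: because binding is reversible, a
system acquires information only at intermediate affinities where occupancy
*fluctuates* — information is maximal where noise is roughly half its maximal
value, and the noise-free limits (permanently bound or never bound) transmit
nothing. The one exception is the "counting" regime — receptors in excess of
signal molecules at very strong affinity — which is noise-free and perfect
but biologically implausible.

## Models

| variant | reactions | output |
| --- | --- | --- |
| `binding` | `S + R ⇌ RS` | `RS` |
| `cascade` | `S + R ⇌ RS`, `RS + D ⇌ RSD` | `RSD` |
| `gene` | `TF + DNA_bs ⇌ TF·DNA_bs`, transcription (rate `k₁`, only while bound), mRNA decay `d₁`, translation `k₂`, protein decay `d₂` | `P` |
| `gene_polymerase` | as `gene`, plus polymerase binding on top of the TF-bound site; transcription requires the full TF·Pol·DNA complex; polymerase copy number redrawn per replicate (negative binomial) to model extrinsic noise | `P` |
| `full_pathway` | `S + R ⇌ RS`, `RS + DNA_bs ⇌ RSD`, gene expression driven by `RSD` | `P` |

Affinities are specified as equilibrium constants `K_eq = k_d/k_a` (molar;
smaller = stronger) and converted to molecule counts through a configurable
reaction volume. Propensities follow mass action: `p_a = k_a/(V·N_A)·N_a·N_b`
for association, `p_d = k_d·N_c` for dissociation, and flat-rate conditional
transcription for a single gene copy (no leaky expression). Every endpoint
sample is drawn by exact simulation (numba-accelerated direct method) from
near-equilibrium initial conditions; the reversible-binding model is also
solved in closed form (detailed balance on the occupancy birth–death chain),
which serves as an independent oracle for the simulator.

## Worked example

Sweep the receptor–signal affinity over `[10⁻⁹, 10⁻⁵] M` for 10 receptors
(10 nM) reading 8 signal levels between 125 and 1000 molecules
(0.125–1 µM), 500 replicate simulations per level:

```python
import numpy as np
from signoise import ModelSpec, affinity_sweep, find_optimum

spec = ModelSpec.binding(n_levels=8)          # 10 receptors, signal levels 125..1000
grid = [10.0**e for e in np.arange(-9, -4.9, 0.5)]
sweep = affinity_sweep(spec, grid, replicates=500, seed=1)
print(sweep.table[["keq_m", "information", "noise", "output_range", "noise_norm"]])
keq, info, noise_frac = find_optimum(sweep)
print(f"optimum: K_eq = {keq:.2e} M, I = {info:.3f} bits, "
      f"noise at optimum = {noise_frac:.2f} of maximum")
```

which prints:

```
   keq_m  information   noise  output_range  noise_norm
   1e-09       0.0113 0.00296         0.072     0.00317
3.16e-09       0.0412 0.00871          0.26     0.00933
   1e-08        0.106  0.0275         0.722      0.0294
3.16e-08        0.236  0.0777          1.84      0.0833
   1e-07        0.413   0.196          3.61        0.21
3.16e-07        0.518   0.407          4.83       0.436
   1e-06        0.434   0.657          3.87       0.704
3.16e-06        0.247   0.884          2.03       0.948
   1e-05        0.105   0.933         0.752           1
optimum: K_eq = 3.16e-07 M, I = 0.518 bits, noise at optimum = 0.44 of maximum
```

Reading the table: at strong affinity (`10⁻⁹ M`) receptors are saturated —
noise, output range and information all collapse; at weak affinity (`10⁻⁵ M`)
binding is rare — noise is maximal (Fano ≈ 0.93) but the output range is
tiny, so information again vanishes. Information peaks in between
(`3.2×10⁻⁷ M`, about 0.52 of the 3 bits available), where the noise level is
≈ 0.44 of its maximum.

The same sweep is available from a shell:

```bash
signoise run config.yaml --out results/ --seed 1
signoise metrics results/ensemble/keq_3.162e-07M.tsv
```

(see `signoise/cli.py` docstring for the config format).

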