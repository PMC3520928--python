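# foldonkinetics

Build discrete kinetic models of protein folding from funneled-landscape
simulation data. The pipeline:

1. **native structure → contact set** — parse Cα coordinates, define a
   foldon partition (contiguous residue segments), and collect native
   contact pairs with sequence-separation-dependent Gaussian widths.
2. **coordinates → macrobasins** — compute per-foldon and global native
   similarity q ∈ [0, 1] per frame; threshold each foldon's q to get a
   binary macrobasin label (e.g. `0101` = second and fourth foldons
   folded).
3. **umbrella windows → free energies** — combine biased windows with a
   self-consistent multistate reweighting estimator to obtain macrobasin
   free energies (in k_BT) at any target temperature.
4. **master equation** — connect sampled macrobasins at Hamming distance 1;
   downhill transitions run at a universal rate k₀, uphill ones carry a
   Boltzmann penalty. The spectral solution gives relaxation rates and
   population dynamics; scanning temperature traces a chevron curve.
5. **fluxes** — cumulative net fluxes between macrobasins (evaluated
   analytically per mode, including the τ → ∞ equilibrium limit), widest-
   bottleneck dominant pathways, and GraphViz DOT flux diagrams.

A fully synthetic data module (Ising-like foldon landscapes with exactly
enumerable 2^N free energies plus a Metropolis umbrella sampler) provides
ground truth for every downstream stage.

## CLI

All stages are exposed through one executable:

```sh
# generate synthetic umbrella windows with known ground truth
foldonkin synth --n-foldons 4 --windows 5 --frames 5000 --seed 1 --out run/

# label frames, estimate free energies over a temperature grid
foldonkin label --windows run/windows/manifest.yaml --out run/
foldonkin freeenergy --windows run/windows/manifest.yaml \
    --temps 0.85:1.15:7 --gauge unfolded --out run/

# rate matrix, chevron curve, fluxes
foldonkin network --free-energies run/fe/fe_1.tsv --k0 1e6 --out rates.tsv
foldonkin chevron --fe-dir run/fe --k0 1e6 --out chevron.tsv
foldonkin flux --fe run/fe/fe_1.tsv --start unfolded --tau inf \
    --out flux.tsv --dot flux.dot

# or the whole pipeline from one config file
foldonkin run --config config.yaml
```

`run` writes `run_manifest.json` recording parameters, seeds and SHA-256
hashes of every output; identical configs and seeds reproduce every file
byte-for-byte.

Example `config.yaml`:

```yaml
output_dir: out
threshold: 0.6
k0: 1.0e6
seed: 1
temperatures: {start: 0.85, stop: 1.15, num: 7}
synthetic: {n_foldons: 4, n_windows: 5, n_frames: 5000}
```

## Units and conventions

* k_B = 1; free energies are in units of k_BT at each table's own
  temperature; the all-zeros (fully unfolded) macrobasin is the F = 0 gauge.
* Rate matrix entry (row b, column a) is the rate a → b; columns sum to
  zero, so probability is conserved.
* Macrobasin labels read N- to C-terminal, `1` = folded.
* Flux matrix entry (a, b) is the cumulative net flow b → a; it is
  antisymmetric and supported only on Hamming-distance-1 edges.
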