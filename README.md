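# coopbind

Quantitative readouts of cooperative nucleic-acid binding by a multidomain
RNA-binding protein — and of the self-association that antagonises it.

TDP-43-like proteins bind GU-rich RNA / GT-rich ssDNA repeats through tandem
RRM domains, and a second protein unit can load onto a long repeat far more
tightly than the first (cooperative assembly).  The folded N-terminal domain
(NTD) of the same protein self-associates head-to-tail.  Whether those two
modes of oligomerisation help or hinder each other is measured through four
independent experimental streams, each of which this package reimplements as
tested, reusable code exercised on synthetic data with known ground truth:

1. **ITC** (`coopbind.itc`) — one-set and two-sets-of-sites binding-heat
   models.  Cumulative heat for two sets of sites:

   `Q = Mt·V0·[ n1·ΔH1·K1·X/(1+K1·X) + n2·ΔH2·K2·X/(1+K2·X) ]`

   with X the free-ligand concentration from the mass balance, and observed
   per-injection heats corrected for the displaced volume,
   `qᵢ = Qᵢ + (dVᵢ/V0)·(Qᵢ+Qᵢ₋₁)/2 − Qᵢ₋₁`.  Cooperativity is quantified as
   the fitted dissociation-constant ratio **K_D1/K_D2** (reported as
   max/min ≥ 1; ≫ 1 means the second unit binds far tighter than the first).
2. **NMR CSP** (`coopbind.csp`) — the weighted amide chemical-shift
   perturbation `Δδ = (0.5·[ΔδH² + (0.14·ΔδN)²])^½` with the 3×SD
   significance threshold, plus after/before peak-height ratios that expose
   interface residues broadened by self-association.
3. **SAXS** (`coopbind.saxs`) — Guinier Rg/I(0), dimensionless Kratky plots
   with the ideal-globule reference point (√3, 3/e), correlation-volume
   molecular weight, P(r)/Dmax by regularized indirect Fourier transform,
   stable-Rg SEC-SAXS frame averaging, and curve comparison
   `χ² = 1/(N−1)·Σ[(Iexp − c·Itheor)/σ]²` with the analytic optimal scale c.
4. **Imaging** (`coopbind.imaging`) — the microtubule-bench **mixing score**
   (spot detection → area/elongation filters → cytoplasm-normalised
   enrichment → per-well regression R²) and nuclear-aggregate scores
   (background-subtracted relative intensity; poly-A mRNA enrichment).

`coopbind.synth` generates ground-truth-labelled inputs for all four streams
(noisy isotherms, perturbed peak lists, Debye bead-model scattering for
extended vs loop-compacted chains, and two-channel cell images whose
per-spot enrichments have a stated correlation); `coopbind.io` reads and
writes the standard formats (ITC CSV, Sparky-style peak lists, 3-column
`.dat` curves, TIFF).

## Worked example

```python
from coopbind import synth
from coopbind.itc import BindingModelTwoSets, fit_isotherm

protocol = synth.default_protocol()           # 0.2 mL cell, 15 uM protein,
                                              # 100 uM oligo, 37 x 1 uL
truth = BindingModelTwoSets(n1=0.25, n2=0.25,  # one oligo saturates 2 monomers
                            K1=1e6, K2=1e8,    # K_D: 1 uM and 10 nM
                            dH1=-8.0, dH2=-12.0)
iso = synth.gen_itc(truth, protocol, noise_sd=0.0)
fit = fit_isotherm(iso, protocol, "two_sets")
print(round(fit.params["n1"] + fit.params["n2"], 3),
      round(fit.cooperativity_index, 1))
```

prints `0.5 100.0`: the fitted total molar ratio of 0.5 oligonucleotide per
protein monomer says each repeat carries two protein units, and the
K_D1/K_D2 ratio of 100 says the second unit binds 100-fold tighter — the
signature of cooperative assembly on a long repeat.

The numbered drivers under `analysis/` run the full narrative on synthetic
data and write tables under `results/` (run `01` first; later scripts read
its outputs):

```sh
python analysis/01_simulate_inputs.py     # all four synthetic datasets
python analysis/02_itc_cooperativity.py   # K_D1/K_D2 + one-set vs two-sets F-test
python analysis/03_csp_mapping.py         # 3xSD CSP flags, broadening ratios
python analysis/04_saxs_compaction.py     # Rg/Dmax/Kratky: open vs looped chains
python analysis/05_imaging_scores.py      # mixing score R^2 vs rho^2, aggregates
```

For instance, `04` reports Dmax ≈ 96/188/265 Å for open 8/16/24-bead chains
against 34/64/121 Å for their loop-closed counterparts — loop closure
compacts the particle at every length — and `05` shows the per-well mixing
score tracking the generating correlation (mean R² ≈ 0.008/0.24/0.64/1.00
for ρ = 0, 0.5, 0.8, 1).

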