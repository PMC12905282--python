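# Methods

This note documents the models, numerical choices and limitations behind
each analysis stream, and what the synthetic generators do and do not
emulate.

## ITC binding models

The cell contains the macromolecule (protein) at total concentration Mt; the
syringe delivers the ligand (oligonucleotide) at concentration Xs in
injections of volume dVᵢ into a cell of active volume V0.  Heats are in
kcal, concentrations in M, association constants K in 1/M, temperatures in K.

**Free ligand.**  For s independent sets of sites the mass balance
`Xt = X + Mt·Σ_s n_s·K_s·X/(1+K_s·X)` has exactly one root in [0, Xt]
(the right-hand side is strictly increasing in X).  It is bracketed with
Brent's method and polished with Newton steps until the residual is below
1e−12·max(Xt, 1e−12).

**Cumulative and injection heats.**  Q follows the one-set/two-sets forms
given in the README.  Observed per-injection heats apply the
displaced-volume correction `qᵢ = Qᵢ + (dVᵢ/V0)·(Qᵢ+Qᵢ₋₁)/2 − Qᵢ₋₁`
(reducing to the simple difference when dVᵢ = 0).

**Dilution convention.**  Concentrations across injections follow the
perfusion model for an overfilled cell, `Mtᵢ = Mt0·e^(−vᵢ/V0)`,
`Xtᵢ = Xs·(1 − e^(−vᵢ/V0))` with vᵢ the cumulative injected volume.  This
is the standard instrument convention consistent with the displaced-volume
heat correction; it is isolated in
`TitrationProtocol.cell_concentrations` so a linear variant could be
swapped in.  The molar-ratio axis is Xtᵢ/Mtᵢ.

**Fitting.**  Weighted nonlinear least squares (lmfit over
`scipy.optimize.least_squares`, tolerances 1e−12) of predicted against
observed qᵢ, with K parameterised as log10 K.  Multi-start initialisation
(≥ 6 starts) derives the stoichiometry guess from the transition midpoint
of the isotherm, ΔH from the first-plateau heat per mole of injectant, and
spans K over several decades around a mid-range Wiseman c (c = K·Mt0·n);
c values outside [1, 1000] trigger a warning that parameters may be poorly
determined.  The independent two-sets model is invariant under relabelling
of the sets, so binding *order* is not identifiable; the cooperativity
index is therefore defined as max(K_D)/min(K_D) ≥ 1.  When two sets are
(near-)equal the model is degenerate — noise can "split" K1/K2 at
essentially no cost — so among starts whose final cost is within 0.5% of
the best, the least cooperative solution is kept, and the analysis driver
additionally reports an F-test of two-sets against one-set: an
unsupported second set means the fitted K_D ratio carries no evidence of
cooperativity.

**Derived quantities.**  Per set, K_D = 1/K, ΔG = −RT ln K with
R = 1.987204259e−3 kcal/(mol·K), and TΔS = ΔH − ΔG.  The reported
stoichiometry nᵢ is per protein monomer, so a repeat that carries two
protein units fits a *total* molar ratio n1+n2 ≈ 0.5 oligonucleotide per
monomer; both that fitted total and the transition position on the
molar-ratio axis are reported, since either may be quoted as "N".

**Default protocol** (the conditions the generators simulate): 0.2 mL cell,
15 µM protein, 100 µM oligonucleotide, 37 injections of 1 µL, 25 °C.
Simulation noise is additive Gaussian per-injection heat noise with
user-set SD and seed; the first-injection artifact exclusion is available
behind a flag (default off, since simulated data have no such artifact).

## Chemical-shift perturbations

`Δδ = sqrt(0.5·[ΔδH² + (0.14·ΔδN)²])` in ppm.  The significance threshold
is 3× the standard deviation (ddof = 1) of Δδ over **all** matched
residues, perturbed ones included — the plain reading of the
figure-caption convention; a median/MAD variant (`robust=True`) is
available when a handful of large perturbations would inflate the
threshold.  Residues unassigned, overlapped or absent in either list are
excluded with a reason rather than entering as zeros.  Peak matching is by
residue identifier only; tracking peaks across crowded spectra is out of
scope.  Peak heights enter ratios as read from the list — no lineshape
fitting or noise-floor normalisation (a normalisation hook exists but
defaults to raw heights, since the acquisition-scan convention of the
source data is not stated).

## SAXS analytics

**Guinier.**  ln I vs q² on the largest low-q window satisfying
q·Rg ≤ 1.3 (default), iterated to a fixed point from the first
positive-intensity point.  Because compact shapes leave the Guinier regime
*within* that window (a solid sphere is ~2% high at q·Rg = 1.3), the
window additionally shrinks while an added q⁴ term both (a) exceeds twice
its own standard error and (b) shifts Rg by more than 0.5%.  On noisy data
the significance gate keeps the full window, avoiding noise-chasing.

**Dimensionless Kratky.**  (q·Rg, (q·Rg)²·I/I0) with the ideal-globule
reference maximum (√3, 3/e ≈ 1.104) returned for overlay; extended chains
plateau above it.

**Correlation volume.**  Vc = I(0)/∫ q·I dq, integrated to
min(0.3 Å⁻¹, 8/Rg) with the segment below the first measured q filled by
the closed-form Guinier integral.  Molecular weight uses the
correlation-volume power law QR = Vc²/Rg with the protein constants
(divisor 0.1231, exponent 1.0, mass in Da); the RNA variant
(0.00934, 0.808) is selectable.  The two calibrations differ materially
and neither is claimed correct for mixed protein/nucleic-acid particles —
treat MW estimates for nucleoprotein bead models as indicative only.

**P(r) / Dmax.**  The distribution is represented directly on a uniform
r-grid (81 points) with p(0) = p(Dmax) = 0 pinned, fitted to
I(q) = 4π·Σ wᵢ p(rᵢ)·sinc(q rᵢ) by bounded linear least squares
(`scipy.optimize.lsq_linear`, positivity on by default) with
second-difference smoothness regularization.  The regularization weight is
chosen once per scan by an L-curve corner rule (falling back to the
minimum-χ² weight when the corner solution misfits grossly) and recorded
in the output.  When Dmax is not supplied, candidates over [2·Rg, 5·Rg] in
2 Å steps are scored by back-transform χ² plus small penalties for
oscillation (total variation of p in excess of the unimodal value 2·max p,
weight 0.1) and negative lobes (weight 0.5); the selected Dmax is the
smallest whose score is within 5% (plus 0.05 absolute) of the best — the
knee beyond which extending Dmax buys nothing.  On an analytic sphere this
recovers 2R within a few percent; for ring-like geometries, whose p(r)
concentrates sharply near Dmax, χ² barely penalises over-long candidates
and Dmax can be overestimated — the open-vs-looped *ordering* is robust,
the looped absolute value is not.  Failure to find any acceptable
candidate raises an estimation error carrying the scan diagnostics.

**χ² and scale.**  `χ² = 1/(N−1)·Σ[(Iexp − c·Itheor)/σ]²` with the
analytic `c = Σ(Iexp·Itheor/σ²) / Σ(Itheor²/σ²)`, which attains the
minimum of χ²(c) exactly.

**Frame selection.**  Per-frame Guinier Rg; the longest contiguous run
whose members deviate < 5% (default) from the run median is averaged with
inverse-variance weights, which can only reduce the pointwise σ.  A single
frame is returned as-is; otherwise runs shorter than 3 frames fail.  The
5% default is a choice — the source convention ("similar and stable Rg")
names no tolerance.

## Imaging scores

Segmentation is deliberately simple and fully parameterised, because the
original detection pipeline is proprietary with unpublished parameters:
nucleus by Otsu threshold on the stain channel plus hole filling;
cell footprint by Otsu on a cytoplasmic channel (union with the nucleus)
or, without one, a dilation band; cytoplasm = cell − nucleus.  Spots are
connected components above an adaptive threshold (cytoplasm median +
6 robust SDs, where robust SD = 1.4826·MAD) inside the cytoplasm.
Width-to-length ratio is the minor/major principal-axis length ratio of
the component.  Filters keep area strictly in (20, 300) px² and ratio
strictly < 0.3 (strict inequalities, matching the printed thresholds).
Enrichment is spot mean / cytoplasm mean per channel, with spot pixels
excluded from the cytoplasm mean.  The mixing score is the R² of the
ordinary least-squares regression of green on red enrichment with spots
pooled per well (one dot per well; a per-cell variant exists behind a
flag).  Nuclear aggregates are found by white top-hat + robust threshold
inside the nucleus; relative intensity sums (intensity − local background,
floored at 0) over aggregate pixels and divides by the integrated nuclear
intensity, with the local background of each aggregate the median of a
2-px annulus around it (other aggregates excluded) — "local background" has
no published definition, so this one is recorded here.  mRNA enrichment is
the mean FISH intensity over aggregate pixels divided by the nuclear mean.

## Synthetic generators

Every generator embeds a machine-readable ground-truth record; recovery
tests read truth only from there.

- **Isotherms**: exact forward-model heats plus Gaussian noise (shared code
  path with the fit, so zero-noise simulation equals the model exactly).
- **Peak lists**: uniform random shift/height backgrounds; the "after"
  list applies coherent shift offsets to a designated perturbed set,
  multiplies heights of a broadened set (factor 0 ⇒ absent), and jitters
  all positions with Gaussian SD 0.005 ppm by default in both dimensions.
- **Bead models**: Debye double sum with a per-bead solid-sphere form
  factor (default bead radius 5 Å, chain spacing 12 Å — order-of-magnitude
  of a protein footprint on nucleic acid; config values, not claims about
  any particular protein).  Exact Rg includes the bead term (3/5)a²; exact
  Dmax adds 2a to the largest centre distance.  The compaction scenario is
  purely geometric loop closure, not a physical model of domain-mediated
  compaction.  σ(q) ∝ sqrt(I/q), scaled so I/σ at the first point equals
  the stated SNR — a heuristic for counting statistics diluted over wider
  annuli at high q.  The default q grid is geometric (0.0025–0.35 Å⁻¹,
  260 points) so large particles keep an adequately sampled Guinier region.
- **Images**: disk nucleus and cell, non-overlapping elongated ellipse
  spots in the cytoplasmic ring with uniform interior intensity
  base·enrichment; per-spot (red, green) enrichments from a bivariate
  normal (mean 3.0, SD 0.5, correlation ρ, truncated below 1.5 so every
  spot stays detectable); optional nuclear aggregates and a FISH channel;
  Poisson counting noise plus Gaussian read noise when noise is on.

**What passing recovery tests show — and what they do not.**  The
generators produce idealised data: spots are uniform ellipses that match
the detector's assumptions, isotherm noise is iid Gaussian, bead geometry
exactly matches the Debye forward model.  Recovery therefore validates the
estimators and their wiring, not robustness to the failure modes of real
data (baseline drift and integration artifacts in ITC, peak overlap and
assignment errors in NMR, interparticle interference and radiation damage
in SAXS, uneven illumination and segmentation bias in microscopy).

## Problem sizes

Defaults used by the test-suite and analysis drivers: 37-injection
titrations; 90-residue peak lists; 240–300-point scattering curves with
8–24-bead models; wells of 4–6 cells of 192×192 px with ~20 spots each.
These sizes were chosen so each recovery statistic (e.g. 50-seed medians)
is stable at a few percent while the whole analysis remains interactive.
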