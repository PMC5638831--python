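# Methods

`wormetab` implements the standard 1H-NMR metabolomics analysis chain used
in soil-ecotoxicology studies of *Eisenia fetida*: spectral preprocessing,
OSC-PLS-DA with permutation validation, STOCSY-assisted assignment,
univariate fold-change statistics, pathway impact analysis and
bioaccumulation bookkeeping. Because raw spectra from such studies are
rarely deposited, the package ships a synthetic-spectrum generator whose
statistical structure matches what the analysis chain assumes; every stage
is tested for parameter recovery against the generator's ground truth.

## Synthetic study generator

A metabolite is a set of multiplets, each a group of Lorentzian lines
(natural NMR line shape; default FWHM 0.002 ppm at a 500 MHz-like
resolution) with binomial intensity ratios and a fixed J-type splitting
(default 0.014 ppm ~ 7 Hz). The bundled library covers 60 metabolites
commonly assigned in earthworm polar extracts, with approximate literature
shifts that deliberately avoid the excluded water band (4.70–5.25 ppm).

A study design draws, per sample:

* concentration of metabolite *m*: `fold(m, group) x LogNormal(0, sigma_log)`
  with `sigma_log = 0.15` by default — positive, multiplicative noise, the
  standard within-group biological-variability model in metabolomics. The
  literature this emulates does not report within-group variance, so 0.15
  is a package default exposed in the design (a ~15% coefficient of
  variation, typical of tissue-extract NMR).
* a global dilution factor `LogNormal(0, 0.15)`,
* a rigid per-sample-per-metabolite chemical-shift jitter
  (`N(0, 0.001 ppm)`), preserving multiplet structure,
* a constant baseline offset `N(0, 0.5)` and additive point noise
  `N(0, 1)`; at the default unit base concentration, peak heights are
  O(100), i.e. an SNR of order 100 for a typical resonance.

Spectra live on a 2^14-point grid over 0–10 ppm. One master seed spawns
named substreams (concentrations, dilutions, jitter, noise) so disabling
one noise source does not perturb the draws of the others. Lines are
evaluated within ±0.75 ppm of their center; the truncated Lorentzian tail
carries ~0.1% of the area, below the noise floor.

What the generator does **not** emulate: realistic J-coupling physics and
second-order multiplets, peak-shape distortions, water/baseline artifacts
requiring phase correction, and ppm-dependent peak overlap density of real
tissue extracts. Passing tests therefore demonstrate the statistical
machinery (normalization, discrimination, validation, recovery), not
robustness to instrumental artifacts.

## Preprocessing

1. **Water exclusion** removes all axis points in 4.70–5.25 ppm.
2. **Adaptive binning** (0.2–8.8 ppm, target mean width 0.015 ppm): the
   cross-sample mean spectrum is Savitzky–Golay smoothed at the bin-width
   scale, bin boundaries are placed at its local minima (minimum spacing
   half the target width), stretches longer than twice the target width
   without a minimum are split uniformly, and bins narrower than half the
   target are merged into the narrower neighbour. Bin values are
   trapezoidal integrals over half-open `[lo, hi)` intervals whose shared
   boundary grid points make the bins exactly tile each contiguous
   segment's integral (conservation is tested at 1e-6 relative). The
   boundaries-at-valleys rule is a fully specified stand-in for published
   adaptive/wavelet binning algorithms whose exact in-house variants are
   not reproducible from the literature.
3. **PQN.** Each sample is scaled to the reference's total integral, then
   divided by the median of its bin-wise ratios to the reference (default
   reference: bin-wise median over all samples; a control-group reference
   is available). The stored quotient is the combined divisor on the
   original scale, i.e. the estimated dilution factor. Bins whose
   reference value sits at the noise floor — below 5 x 1.4826 x MAD of the
   reference about its median — are excluded from the quotient median:
   near-empty bins have arbitrary ratios and would otherwise dominate the
   median for sparse spectra. If that guard would exclude more than 95% of
   bins the (looser) positivity guard of 1e-12 x max is used instead. PQN
   is exactly idempotent for samples that are scaled copies of one shape;
   with biological noise the re-estimated reference shifts slightly, so a
   second pass changes quotients at the percent level (both are tested).
   Note one intrinsic property of total-signal normalization: when dosing
   raises the summed signal, unaffected metabolites are scaled slightly
   down in dosed samples, so small apparent decreases in untouched
   metabolites can accompany large planted increases.
4. **Mean-centering** stores column means for back-transformation of
   loadings. PQN precedes centering, the usual order.

## Multivariate modelling and validation

* **PCA** is SVD-based with a deterministic sign convention
  (largest-magnitude loading element positive), checked against an
  eigendecomposition oracle.
* **OSC** removes components of X-variation orthogonal to the dummy-coded
  class matrix Y: starting from the first PC score, the score is projected
  out of the class space, weights regressed, and the pair iterated to
  convergence; X is deflated by the final (exactly Y-orthogonal) score.
  One component is removed by default. Non-convergence within `max_iter`
  is flagged, not fatal. OSC never increases the Frobenius norm, and the
  removed fraction `r2x_removed` is reported.
* **PLS-DA** is NIPALS PLS2 with X-only deflation against the centered
  class-membership matrix; coefficients `B = W (P'W)^-1 Q'`;
  `R2Y = 1 - ||Yc - XB||^2 / ||Yc||^2` is non-decreasing in the component
  count. Predictions agree with an independent PLS implementation to 1e-6
  in tests. The component count defaults to maximizing Q2Y up to 3 when
  not set.
* **Q2Y** comes from repeated stratified two-fold cross-validation (50
  repeats by default) with PRESS and total SS pooled over repeats and
  folds. Centering — and OSC, when enabled — are re-fit inside each
  training fold, so the default Q2Y is leakage-free; a filter-once variant
  (`refit_osc=False`) is provided because most historical chemometrics
  workflows filtered the full matrix before CV. A caveat found while
  validating: with two-fold CV of 10+10 studies the OSC refit sees only
  five samples per class and becomes noisy enough to depress Q2Y even for
  strong effects; OSC genuinely helps (and is tested to help) when a large
  class-orthogonal confounder is present. Q2Y > 0.5 is the conventional
  significance threshold for group separation.
* **Permutation testing** uses Q2Y at reduced CV repeats (7) as the
  statistic, evaluated with a shared fold-assignment stream for the
  observed and every permuted labeling, making the test exact;
  `p = (1 + #{null >= observed}) / (n_perm + 1)`, so 2000 permutations
  floor at 1/2001 ~ 5e-04. Calibration under the null (rejection rate at
  0.05 within [0.02, 0.09] over 200 datasets) is part of the acceptance
  suite. The reported Q2Y uses the full repeat count.
* **S-plot / loading pseudo-spectrum**: per-feature covariance and
  correlation with the first predictive score; under mean-centered (not
  unit-variance) scaling the covariance is already in the bins' intensity
  units, so the pseudo-spectrum height is the back-scaled loading.
  Features are flagged when |r| exceeds the two-sided Pearson critical
  value at alpha = 0.05 with n-2 df; rendering is restricted to the
  0.4–4.3 and 5.7–9.4 ppm windows. Score-plot ellipses use Hotelling's T²
  (a rendering convention; the bivariate-normal alternative differs
  slightly at small n).

## STOCSY

Pearson correlation (and covariance) of a driver bin against all bins
across samples, computed on the normalized, uncentered matrix (centering
is implicit in Pearson). Resonances of one molecule share a concentration
and correlate near 1 — exactly 1 in the noiseless limit, > 0.9 at the
generator's default noise (both tested with lactate's 1.33/4.11 ppm
multiplet pair). The driver resolves to the half-open bin containing the
requested shift. The full 2D matrix is capped (default 2000 features) to
bound memory.

## Univariate layer

Metabolite values are sums of bin integrals whose midpoints fall in the
assignment windows. Fold change is mean(dosed)/mean(control); the test is
Student's pooled-variance t (Welch available by flag); BH adjustment is
applied within each treated-vs-control comparison across metabolites
(matching the convention of per-comparison table columns), and is checked
against a brute-force step-up oracle. Stars follow raw p (* 0.05,
** 0.01, *** 0.001) — the conventional table notation — while q is
reported alongside; a flag switches stars to adjusted p.

## Pathway impact

Pathways are undirected, unweighted compound graphs (directionality is
deliberately not modelled; relative betweenness does not need it and the
edge-list format stays trivial). Node importance is raw betweenness
centrality normalized to sum to 1 across the pathway, with a uniform
fallback when every centrality is 0 (complete or edgeless graphs); the
impact of a hit set is the summed importance of matched nodes — sum
normalization, matching the published description of the topology-impact
score (an alternative normalizes by the maximum centrality; the sum keeps
impact = 1 exactly when all nodes are hit). Enrichment is the upper-tail
hypergeometric probability, verified exhaustively for universes up to 12
compounds. The default universe is the union of library compounds; a
reference list (e.g. the 43 assigned metabolites) can be supplied. A toy
library of six literature-shaped pathways over the default metabolite
names ships for tests and demos; real libraries load from edge-list CSVs.

## Bioaccumulation

BAF = organism concentration (mg/kg dry weight) / soil concentration
(mg/kg); report tables round to 3 decimals. Concentrations are consumed
as group means (per-replicate input aggregates by mean). Survival is
1 - deaths/initial over the exposure. Soil invertebrates concentrate Cd
(BAF >> 1, metallothionein binding) but exclude Pb (BAF << 1), which the
summary flags (Pb < 0.3, Cd > 10) make explicit.

## Problem sizes and determinism

The test suite and demo runs use 8–10 samples per group, the 43-metabolite
library, 2^14-point spectra and ~540 bins; permutation counts are 2000
where the floor matters and smaller elsewhere. Every stochastic routine
takes an explicit seed; the pipeline writes a config snapshot and SHA-256
hashes of all artifacts, and re-running a config with the same seed
reproduces every hash.

## Known limitations

* The adaptive-binning rule is a documented substitute for in-house
  algorithms that cannot be reproduced exactly from the literature.
* OSC-then-PLS is implemented (not integrated O-PLS); multi-class models
  beyond pairwise dose-vs-control are out of scope, as are STOCSY
  variants (STORM/iSTOCSY) and quantitative (GSEA-like) enrichment.
* PQN idempotence and dilution recovery are exact only in the pure-scaling
  limit; with biological variation both hold approximately (tested at 5%
  and Spearman rho > 0.95 respectively).
* The bundled pathway library is a test-scale toy; real analyses should
  load a curated edge-list library.
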