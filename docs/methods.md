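# Methods

This note documents the statistical methods implemented in `mulard`, the
default parameter values, and the reasoning behind the main design
decisions. Everything here is reproducible from the package alone.

## 1. Study design being modeled

Mule ducks are produced by crossing common-duck dams with Muscovy sires and
are sterile, so crossbred traits cannot be measured on the purebred
selection candidates. The analysis chain assumes:

- a crossbred population (default 1422 animals) with known dam and sire,
  dams nested within sires through the mating design;
- two purebred pedigrees: the common dam line (default 596 animals, of
  which 382 are dams of recorded crossbreds) and the Muscovy sire line
  (default 201 animals, 56 sires of crossbreds), each up to 5 generations
  deep;
- a fat-liver melting rate around a mean of 35.6 with phenotypic standard
  deviation 14.7 (units: % melted), measured directly (`mMR`) and/or
  predicted from NIR spectra (`pMR`);
- a single cross-classified fixed effect (hatch/slaughter group, default
  12 levels).

## 2. Crossbred sire–dam model

For t traits on n crossbreds:

    y = Xb + Z_D u_D + Z_S u_S + e

- `u_D ~ N(0, A_D ⊗ G_D)` — dam-line additive effects, `A_D` the
  numerator relationship matrix of the common pedigree;
- `u_S ~ N(0, A_S ⊗ G_S)` — sire-line additive effects;
- `e ~ N(0, I ⊗ R)` — the residual, which absorbs the crossbred
  Mendelian-sampling variance because crossbreds appear only through their
  parents.

Partial heritability of trait i for line L:
`h²_L,i = G_L[i,i] / (G_D[i,i] + G_S[i,i] + R[i,i])`. On this
parameterization a dam-line partial h² of 0.20 corresponds to a purebred
h² of 0.40 (factor 2) and a sire-line 0.10 to 0.20–0.40 (factor 2–4,
depending on the assumed crossbred/purebred genetic correlation);
`genetic_model.rescale_heritability` implements the conversion. Genetic
correlations within a line are ordinary correlations from `G_L`.

### Gibbs sampler

Flat priors on b, `G_D`, `G_S`, `R`. Full conditionals:

- fixed-effect level l: normal with mean = average residual of its
  records, covariance `R / n_l`;
- animal j of line L: normal with precision
  `n_j R⁻¹ + a^{jj} G_L⁻¹` where `a^{jj}` is the diagonal of the sparse
  `A⁻¹` and the mean collects record residuals and the pedigree
  neighbours (single-site update);
- `G_L | u_L`: inverted Wishart with scale `U_L' A_L⁻¹ U_L` and degrees
  of freedom `q_L − t − 1` (flat-prior form);
- `R | e`: inverted Wishart with scale `E'E` and df `n − t − 1`.

The location sweep is JIT-compiled with numba (manual t×t Cholesky and
triangular solves, t ≤ 2 in practice); inverted-Wishart draws use
`scipy.stats.invwishart` with jitter escalation if a scale matrix is
numerically singular. Default chain: 100 000 iterations, 20 000 burn-in,
no thinning; the validation runs in this repository use 20 000 / 4 000,
which gives posterior standard deviations of ~0.03 on partial h² at the
default population size. Derived quantities (h², correlations) are
computed per kept sample and then averaged, so the reported posterior
means and SDs are of the ratio, not ratios of means. Reproducibility: one
user seed feeds a `SeedSequence`; sub-seeds for the numba RNG and scipy
are reduced modulo 2³¹−1.

Diagnostics: effective sample size (autocorrelation-sum estimator) and
split-chain R-hat are provided; `check_normality` screens each trait with
a Kolmogorov–Smirnov test against a fitted normal before analysis.

### Pedigree machinery

`A` by the tabular method, inbreeding by the Meuwissen–Luo algorithm, and
`A⁻¹` by Henderson's rules with exact inbreeding; the Mendelian-sampling
variance `D_j` uses the parental inbreeding coefficients. `A⁻¹` is stored
sparse (CSR) and is the only pedigree object the sampler touches.

## 3. Chemometrics

- **Preprocessing** (`spectra`): operator order is trim to the working
  window (default 800–2500 nm) → average replicates (6 surface scans or 3
  ground-sample scans per liver) → scatter correction → derivative.
  Scatter corrections: standard normal variate (SNV, per-spectrum
  standardization, ddof = 1), quadratic detrend, or multiplicative
  scatter correction (MSC, regression on the mean spectrum). Derivatives
  are gap–segment: boxcar smoothing over a segment (default 5 points)
  followed by a finite difference across a gap (default 10 points),
  applied recursively for second order; a Savitzky–Golay variant is
  available. Points lost at the edges are dropped, and the wavelength
  grid is re-centred accordingly.
- **Calibration** (`chemometrics`): PLS1 by NIPALS with centred data;
  coefficients via `W (P'W)⁻¹ q`, so full-rank PLS equals least squares.
  Calibration samples are chosen by Kennard–Stone on PCA scores
  (components covering ≥ 99 % variance). Model size is chosen by 5-group
  seeded cross-validation with a one-standard-error parsimony rule.
  Reported statistics follow NIRS conventions: SEC with n − k − 1 degrees
  of freedom, SECV from the cross-validation residuals, SEP as the
  bias-corrected standard deviation (ddof = 1) of external-validation
  residuals, and R² as the squared correlation of fitted vs observed.
  `validate_external` refuses sample-id overlap between calibration and
  validation sets.
- **Recipe screening**: `default_recipe_grid` enumerates derivative
  orders 0/1/2 with gap-and-smoothing spans up to 20 points crossed with
  the four scatter treatments (44 recipes), ranked by SECV.

## 4. Simulator

`simdata` draws pedigrees generation by generation (founders first, then
offspring of random earlier-generation parents), simulates breeding values
by the recursive parent-average + Mendelian-deviation scheme (so their
covariance is exactly `A ⊗ G`), builds crossbred phenotypes as
`mean + fixed level + u_dam + u_sire + e`, and renders spectra with a
linear forward model: absorbance = Σ (constituent/100) × Gaussian band
signature, plus a random quadratic baseline, multiplicative scatter,
offset and white noise. Composition (dry matter, lipid, protein, ash,
melting rate) is derived from a shared latent "fat-melt disposition" so
the spectra are informative about, but not deterministic for, the melting
rate.

Default artifact levels (`noise_sd` 0.025, scatter 0.05/0.02,
`baseline_sd` 0.05) were chosen a priori so that a realistic calibration
(R² ≈ 0.8, SECV ≈ 6) emerges rather than a trivially perfect one. The
band library for the melting rate is synthetic — placed in lipid-overtone
regions — and is a modeling convenience, not spectroscopy.

`bivariate_config` builds two-trait generating values from heritabilities
and genetic correlations per line. Its residual correlation default of
0.9 is derived, not tuned: for a measured trait and its NIRS prediction
on the same liver, a phenotypic correlation of about 0.93 together with
h² of 0.2 (dam) / 0.1 (sire) and genetic correlations around 0.9 implies
a residual correlation near 0.9.

Deviations from a field study worth noting: the single fixed effect is
assigned by rotation rather than by hatch blocks, matings are random
within the nesting structure, and liver-weight truncation (300–830 g) is
available but off by default.

## 5. Selection index

`selection_index` solves `P b = g` for index weights and reports accuracy
`r = sqrt(b'g / σ²_A)` with validity checks (P positive definite,
accuracy ≤ 1, non-negative quadratic form). `problem_from_components`
assembles P and g from posterior `G_D`, `G_S`, `R` for either phenotypic
or genetic predictors.

## 6. Validation strategy

Unit tests check each primitive against an independent oracle: tabular A
vs gene-dropping Monte Carlo, sparse `A⁻¹` vs dense inversion, PLS vs
ordinary least squares and scikit-learn, SECV vs a hand-rolled held-out
loop, gap-segment derivatives vs brute force, the Gibbs sampler vs a
one-way ANOVA estimator and vs full numerical integration of the
flat-prior posterior on a small dataset, and index accuracy vs grid
search over weights. The recovery suite (`tests/test_acceptance.py`)
re-estimates the generating values (partial h² 0.20/0.10, genetic
correlations 0.97/0.95, dam-EBV rank agreement > 0.90) from full-scale
simulated populations and requires the truth to fall within two posterior
standard deviations.
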