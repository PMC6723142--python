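# Methods

This note documents the statistical machinery behind `arcgp`: the
models, the numerical choices, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
package's known limitations.

## Kernels

All marker-derived kernels operate on a lines × features matrix. By
default marker columns are centered and scaled to unit sample SD before
kernel construction (`center_scale`); constant columns cannot be scaled
and are dropped with a warning. Scaling is exposed as a flag because the
optimal arc-cosine depth can change with the scaling of the marker
matrix; scaled input is the default for GB, GK and AK alike.

- **GB** `= XX′/p`. No free parameters.
- **GK** `= exp(−h·d²/q)`. The median `q` is computed over strictly
  off-diagonal pairs only; including the diagonal zeros would bias the
  median downward. Identical lines everywhere (`q = 0`) are an error —
  the kernel is undefined, not salvageable.
- **AK**: layer 1 from the angle/norm formula, deeper layers by the
  recursion. The arccos argument is clipped to [−1, 1] before
  evaluation: floating-point round-off on (nearly) identical lines
  would otherwise produce NaN. A zero-norm feature row (possible after
  centering) makes the angle undefined and raises an error naming the
  line — silently jittering genotypes would corrupt the similarity
  semantics. Because `J(0) = π`, the diagonal `AK^l(i,i) = ‖x_i‖²` is a
  fixed point of the recursion at every depth; this is asserted in
  tests and relied on nowhere else. AK matrices are *not* rescaled
  (e.g. by their mean diagonal) before entering the mixed model; the
  prior resolution described below makes rescaling unnecessary, and a
  flag-free default keeps kernels comparable with their definitions.

Kernel validity is checked as symmetry to 1e−10 relative tolerance and
smallest eigenvalue ≥ −1e−8 × largest. When a decomposition is needed,
eigenvalues below 1e−10 × λ_max are truncated to exactly zero
(reduced-rank sampling); more negative eigenvalues are an error, not a
repair target.

Observation-level kernels are realized by index gathering
(`K1[a,b] = G[line(a), line(b)]`) rather than forming dense incidence
matrices; the interaction kernel zeroes cross-environment entries,
which is exactly the Hadamard product with the environment-block
indicator.

## Bayesian fitting

`gibbs_fit` samples the joint posterior of
(μ, β, {u_r}, {σ²_r}, σ²_ε) under flat priors on the fixed effects and
scaled inverse-χ² priors on every variance. Each random effect is
sampled in the eigenbasis of its kernel — one eigendecomposition per
kernel per fit, after which every Gibbs update is O(n²) (a matrix-vector
product). Missing phenotypes are imputed by data augmentation each
iteration; the reported prediction for every record is the posterior
mean of `μ + Xf β + Σ_r u_r`.

Priors: df = 5 for every variance component. Unless given explicitly,
the scale of each component is resolved so that the prior *mode* assigns
equal variance shares to every random term and the residual, summing to
the sample phenotypic variance; each term's share is divided by the mean
diagonal of its kernel, so a kernel with diagonal ≈ p (AK) and a kernel
with diagonal ≈ 1 (GK) receive comparable prior mass on the same
effective variance. Setting df = ∞ with explicit scales freezes the
variances — used only for the closed-form BLUP cross-checks.

Chain defaults are 30,000 iterations, 5,000 burn-in, thinning every 3
(≈ 8,333 retained draws). The test-suite and the worked examples use
reduced chains (2,000–8,000 iterations) — at the test problem sizes the
posterior is well mixed long before the default chain length, and the
BLUP oracle test bounds the residual Monte-Carlo error explicitly.
Identical seeds give bit-identical results on a given platform (one
`numpy` Generator drives the whole chain).

In the G×E model, environments are fixed effects: the intercept is
retained and the first environment's indicator is dropped for
identifiability, so β holds differences from the first environment.

## Marginal likelihood and hyperparameter selection

`m(y)` for the one-kernel model integrates u and μ analytically (both
Gaussian; μ flat) and the remaining two-dimensional integral over
(σ²_u, σ²_ε) numerically: a 61 × 61 logarithmic grid spanning
[1e−4, 1e2] × var(y) on the residual axis and the same span divided by
the mean kernel diagonal on the genetic axis, trapezoid weights in
log-variance space, log-sum-exp accumulation. One eigendecomposition
makes each grid point O(n). Against an independent dense-quadrature
oracle the default grid agrees to ~3e−7 log-units on n = 5 problems
(the test asserts 1e−3).

Layer selection evaluates MML(1), then repeatedly applies the
recursion: while MML(l+1) > MML(l) the deeper kernel is accepted; the
first non-improvement (ties included) stops the search and selects l.
`l_max = 25` bounds the loop. Bandwidth selection is the argmax of the
same marginal likelihood over a logarithmic grid, default 10 points in
[0.01, 10]. Both return deterministic results given the data. For the
G×E model, selection uses the pooled training records with the
main-effect kernel only (interaction reuses the selected kernel);
training records are centered per environment first, because the
selection likelihood carries a single intercept while environment means
are fixed effects in the fitted model.

## Cross-validation protocol

`RANDOM_LINES` partitions sample round(f·n_lines) training lines; a
line is entirely training or entirely testing. `CV2` masks
(1 − f) of the cells independently within each environment, redrawing
any draw that would leave a line with no training observation anywhere —
the scheme under which the G×E model can borrow a line's records from
other environments. Hyperparameters (l, h) are re-selected inside every
training partition; selection on the full data would leak test
information into the kernel choice. Accuracy is the within-environment
Pearson correlation over test records, averaged over partitions
(partition-level averaging, not pooled-then-correlated). Methods are
compared by a paired one-sided t-test over partitions; if the paired
differences have zero variance, p is 0, 1 or 0.5 according to the sign
of the common difference. A partition whose fit fails is logged and
skipped, and the skip count is reported with the results.

## Synthetic data

The generator emulates multi-environment breeding-trial data:

- **Markers**: biallelic dosages {0,1,2}; per-marker allele frequency
  uniform on a configurable range. By default lines are unrelated
  (binomial draws). With `n_founders` set, lines are inbred
  founder-haplotype mosaics (blocks of consecutive markers copied from
  random founders, doubled), producing the family-level kinship of a
  real panel. The preset scenarios use 4 founders: the resulting
  kinship values spread widely around zero, which matters below.
- **Phenotypes**: `y = μ + env + g + u2 + ε` with
  `g ~ N(0, σ²_a·K_add + σ²_epi·K_epi)`, where `K_add` is GB on
  centered/scaled markers and `K_epi = GB ∘ GB` is the Hadamard square —
  exactly the covariance of iid effects on all pairwise marker
  products (verified in tests against an explicit pairwise-feature
  construction). Interaction deviations u2 are drawn independently per
  environment, giving between-environment genetic correlation
  σ²_g/(σ²_g+σ²_ge). All kernels are normalized by their mean diagonal
  so the σ² parameters live on the phenotypic scale.
- **Spectra**: smooth log(1/R) curves on the 400–2500 nm grid at 20 nm
  (106 wavelengths): a shared mean curve with broad absorption bands, a
  low-rank line-specific deviation (loadings on a few Gaussian bumps,
  optionally mixed with supplied genetic values), and small noise.

Preset study conditions: heritability 0.5 throughout;
`additive_scenario` (σ²_a = 1), `epistatic_scenario`
(σ²_a = 0.15, σ²_epi = 0.85), `ge_scenario` (3 environments,
σ²_ge = 0.4, between-environment genetic correlation ≈ 0.71). Default
panel shape is 300 lines × 1,000 markers; tests run reduced sizes
(40–300 lines, 60–400 markers) chosen so the full suite completes in
well under a minute of sampling time per check.

A point worth making explicit: with *unrelated* lines the Hadamard
square of a near-diagonal GB is itself near-diagonal, so epistatic
effects are essentially unpredictable for any kernel — linear or not —
and no method comparison can distinguish architectures. Predictable
epistasis requires relatedness, and the *spread* of kinship values
(including negative values after scaling) is what makes the squared
covariance genuinely nonlinear in GB and gives the nonlinear kernels
their advantage. This is why the preset scenarios simulate few-founder
panels; it mirrors the fact that real benchmark panels are families of
related breeding lines, not random populations.

What the generator does **not** emulate: realistic linkage
disequilibrium decay or coalescent history, dominance, selection,
pedigree-recorded crossing schemes, multi-trait architectures, NIR
scatter artifacts or instrument noise structure. Passing tests
demonstrate internal correctness and the qualitative kernel-comparison
patterns under these idealized conditions — not performance guarantees
on any particular real data set.

## NIR preprocessing

First and second Savitzky–Golay derivatives of log(1/R) spectra, scaled
by the wavelength step (units per nm, per nm²). Defaults window = 11,
polyorder = 2 — the smallest common smoothing-derivative configuration;
both are exposed as options since published analyses rarely state them.
Edge wavelengths where the full window does not fit are dropped rather
than padded: padded derivatives are artifacts with no spectral meaning.
The filter is exact for polynomial spectra up to the polynomial order
(asserted to 1e−10).

## Known limitations

- The Gibbs sampler is single-chain; no formal convergence diagnostics
  are computed. The BLUP and recovery tests bound Monte-Carlo error for
  the covered regimes; very small variance ratios may need longer
  chains.
- Bandwidth selection is a grid argmax of the marginal likelihood, not
  a continuous optimizer; resolution is limited by the grid.
- The marginal-likelihood quadrature assumes the variance posterior is
  contained in [1e−4, 1e2] × var(y) (after the kernel-diagonal
  rescaling); pathological inputs outside that envelope would need
  wider spans.
- Pedigree kernels are accepted as precomputed matrices and validated
  (symmetry/PSD); building the A-matrix from pedigree records is out of
  scope, as is marker QC/imputation (inputs must be complete).
- CV1 (lines new in every environment) and leave-one-environment-out
  schemes are not implemented.
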