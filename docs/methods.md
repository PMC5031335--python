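# Methods

## The statistic and its null distributions

For one SNP set, the score-type statistic is `s = z′ G W G′ z` with
`z = y − μ` the residuals of the covariate-only null fit and
`W = diag(w)` variant weights. Internally `s = ‖V′z‖²` with
`V = G diag(√w)`; `V` is computed once per set and reused for every
permutation, which makes a permutation batch a single matrix product.

Two null references are available:

* **Asymptotic** (`asymptotic_pvalue`): `s ~ Σ λᵢ χ²₁` with λ the non-trivial
  eigenvalues of the null-covariance-weighted kernel — for quantitative
  traits `σ̂² · eig(V′(I−H)V)` with `H` the covariate hat matrix and
  `σ̂² = RSS/(n−k−1)`; for binary traits the same projection taken in the
  metric of `D = diag(μ̂(1−μ̂))`. The Gram matrix is formed on the smaller of
  the m×m / n×n sides and eigenvalues below `10⁻¹⁰·λ_max` are dropped.
  The default tail evaluator is the modified three-moment match to a
  noncentral chi-square (fast; matches the exact tail to a few percent in
  the regimes we use it). `method="imhof"` inverts the characteristic
  function numerically: the integrand is split into Fourier components
  `sin(φ)cos(qu/2) − cos(φ)sin(qu/2)` and integrated with QAWF-weighted
  quadrature after a short non-oscillatory head interval, with the
  one-eigenvalue case reduced analytically to a scaled chi-square. Against
  5×10⁵-draw Monte Carlo references the Imhof path agrees to Monte-Carlo
  precision across the tail (checked in the test suite via the
  single-variant closed form and mixture fixtures).

* **Permutation**: `z` is permuted uniformly; `r` counts permutation
  statistics **strictly greater** than `s` (ties, a measure-zero event for
  continuous traits, therefore favour the set). Permuting the residuals
  rather than raw `y` is exactly equivalent without covariates and keeps the
  null adjustment fixed with them; covariate-bearing permutation analyses
  should be read as residual permutation tests.

## The adaptive stopping rule

Parameters (`StoppingConfig`): genome-wide level `alpha_e`, set count
`m_sets` (so `alpha_p = alpha_e/m_sets`), CI tail mass `ci_level`
(default `alpha_p`), budget `b` (default `5/alpha_p`, hard floor
`1/alpha_p`), batch size `batch = 1000`, `refine`, `seed`.

After each batch the engine checks, in order: the r = 0 negative-binomial
rule `(1−α_p)^B < α_p` (stop with `p̂ = 1/B`); the r = B rule
`α_e^B < α_p` (stop with `p̂ = 1`); otherwise CI exclusion
`|p̂ − α_p| > z₁₋α/2 √(p̂(1−p̂)/B)`. The ordering of the three checks within
a batch is a design choice; they are mutually exclusive given (r, B), so it
only fixes which reason is reported. The "α confidence interval" is
interpreted as tail mass (coverage 1−α): decreasing `ci_level` widens the
interval, defers stopping, and tightens agreement with the fixed-budget
estimate — the direction the accuracy-vs-cost experiments verify.
At the budget with 0 < r the estimate is `r/B` (not `(r+1)/(B+1)`); `1/B`
is reserved for r = 0. In refine mode any stop that would report
`p̂ < α_p` is ignored, so significant sets reach the floor `1/b`.

Per-set randomness comes from `SeedSequence(entropy=seed, spawn_key=(i,))`
for set index i: scans are bit-reproducible under any thread count or
execution order, and stop decisions are deterministic functions of (r, B,
config), so replaying a stream reproduces a result exactly.

## The synthetic evaluation inputs

The generator emulates the statistical regime of a calibrated coalescent
panel of a European-LD 200-kb region with 10,000 haplotypes, without
reproducing any specific external panel:

* site frequencies from the neutral spectrum density ∝ 1/x truncated to
  [1/H, 0.5] (inverse-CDF sampling), giving a rare-variant-rich spectrum
  (most sites below MAF 0.05);
* linkage disequilibrium from a mosaic copying process: an independent
  founder realisation of the target frequencies, then each haplotype copies
  founder segments with per-site switch probability 0.05 (≈1-kb expected
  segments at the default density of 4,000 sites per 200 kb, chosen to match
  the variant density of coalescent panels used for rare-variant power
  studies); monomorphic columns are dropped.

Phenotypes follow `y = α + Gβ + ε` with ε standard normal (power and
calibration runs) or Student-t with 5 df (heavy-tailed type-I runs). Test
regions are uniformly placed 5-kb windows; ⌈0.2 · #rare⌉ of a region's rare
variants are causal, 80 % with positive sign, and
`|β| = max_effect · |log₁₀ MAF| / 4`, anchoring the configured maximum
effect at MAF 10⁻⁴ (the convention of standard rare-variant power tools;
the evaluated maxima are {0.4, 0.8, 1.2, 1.6, 2.0}). The intercept defaults
to 0 — it is absorbed by the null fit and cannot affect any test.

What the generator does **not** model: real LD block structure and
recombination hotspots, population stratification, relatedness, genotyping
error, and case/control ascertainment. Passing tests therefore demonstrate
the engine's statistical behaviour (calibration, early-stopping accuracy,
ordering of methods), not power numbers transferable to any particular
cohort; absolute power depends on the haplotype panel used.

## Experiment protocols and problem sizes

All evaluation runs use a scaled panel of 2,000 haplotypes × ~1,400 sites
over 200 kb; the sizes below were chosen once so the full suite runs on a
single CPU in minutes.

* **Null calibration**: 2,000 single-set replicates at n = 500, Gaussian
  noise, α = 0.05. The permutation budget here is b = 1000 (not the scan
  default 5/α = 100): with `p̂ = r/B` and the decision `p̂ ≤ α`, a
  B-permutation test rejects a uniform null with probability
  `(⌊αB⌋+1)/(B+1)` — 0.0594 at B = 100 purely from resolution, 0.051 at
  B = 1000 — so B = 1000 measures the engine rather than the granularity
  of r/B.
* **Heavy-tailed type I**: 20 experiments × 20 sets at n = 500 with t(5)
  noise; both methods thresholded at the Bonferroni per-set level
  α_p = 0.05/20; totals summed over experiments.
* **Accuracy vs cost**: one 200-set cohort (n = 250, 15 % of sets causal at
  max effect 1.2, a composition that spreads set p-values across the whole
  scale), standard fixed budget b = 10⁵ versus the adaptive engine in refine
  mode at ci ∈ {0.05, 2.5×10⁻⁶, 2.5×10⁻¹¹}. The adaptive runs replay the
  *same* per-set permutation stream at every CI level (the standard run uses
  an independent stream), so level-to-level differences isolate the stopping
  rule; the agreement metric is max |log₁₀(p̂/p_standard)| over sets above
  the 1/b floor. A consequence of stream sharing: sets that exhaust the
  budget at two CI levels contribute identically to both, so the worst-case
  sequence can tie between adjacent levels when the same saturated set
  dominates.
* **Power**: per-test single-set runs (α_p = α, b = 5/α), cells = fraction
  of replicates with p ≤ α; sample-size requirements are read off the grid
  as the first n reaching the target power.

## Numerical and degenerate-input choices

* MAF is folded (≤ 0.5) and computed over non-missing calls; the rare filter
  keeps `0 < maf < threshold` strictly (threshold 0.05 by default).
  Monomorphic variants are removed — any finite weight density gives them
  zero contribution anyway.
* Missing dosages are mean-imputed (observed column mean = 2·MAF for
  minor-counted columns) only at statistic time; stored data stay lossless.
* An all-zero kernel yields p = 1 with a warning; s = 0 yields p = 1;
  an all-zero residual vector gives s = 0 (valid, not an error).
* Logistic null fits that separate raise an error naming the remedy; rank
  deficient designs raise an error naming the collinear columns.
* Budgets below `1/α_p` are rejected before any permutation is drawn.

## Known limitations

* No SKAT-O style optimal burden/variance-component combination and no
  small-sample moment corrections; the asymptotic path exists as the fast
  comparator, the permutation path as the accurate one.
* Only the weighted linear kernel; no kinship/mixed-model adjustment.
* PLINK support is bed v1 SNP-major (the modern default); sample-major
  files and VCF/BGEN/pgen inputs are out of scope.
* Wall-clock comparisons are deliberately replaced by permutation-count
  comparisons, which are hardware-independent and assertable.
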