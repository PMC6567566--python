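# Methods

## Model

For each trait the observation of individual *k* of clonal genotype
*g* at food level *f* is modelled as

    y_gfk = mu + alpha_f + u_g + w_gf + e_gfk

with food a fixed factor and genotype and the genotype-by-food (G×F)
interaction independent zero-mean normal random effects with variances
sigma2_G, sigma2_GxF, and residual variance sigma2_e.  The design of
interest is a small factorial: by default 5 genotypes × 2 food levels
(2.0 and 0.2 mg C L⁻¹) × 10 individuals per cell.  Assumptions:
independent individuals within cells, homoscedastic residuals across
cells, normal random effects.  Variance-stabilising transforms (below)
are applied where a trait's raw distribution violates the last two.

## Variance-component estimation

**EMS (method of moments).**  On balanced data the expected mean
squares of the unrestricted two-way mixed model give

    sigma2_e   = MS_error
    sigma2_GxF = (MS_GxF − MS_error) / r
    sigma2_G   = (MS_G − MS_GxF) / (r·f)

with *r* replicates per cell and *f* food levels.  Negative solutions
are truncated to zero — variance-component tables conventionally print
exact 0.00 entries — and truncation happens *before* any downstream
heritability computation.  F-tests follow the unrestricted-model
convention: genotype and food over the interaction mean square, the
interaction over the residual.  The restricted-model convention
(genotype over the residual MS, sigma2_G from MS_G − MS_error) is
available via `convention="restricted"`.

**REML.**  The restricted likelihood is profiled over sigma2_e and
maximised over the variance ratios (sigma2_G/sigma2_e,
sigma2_GxF/sigma2_e) with L-BFGS-B under non-negativity bounds,
multi-started from the EMS solution (when the design is balanced) plus
fixed fallback points.  Starting at the EMS solution matters: on
balanced data with interior optima REML and EMS coincide analytically,
and the optimiser confirms this to machine precision.  Boundary
estimates (a component exactly 0) are legitimate results, not errors.
With a single food level the interaction indicator coincides with the
genotype indicator, so sigma2_GxF is pinned at zero rather than left
unidentifiable.  The implementation is cross-checked in the test suite
against an independent mixed-model fitter (statsmodels `MixedLM`) on
unbalanced data.

## Heritability, CV, bootstrap

Broad-sense heritability is H² = V_g / V_T with V_g = sigma2_G.  V_T
defaults to sigma2_G + sigma2_GxF + sigma2_e — heritability defined
over the random variation, excluding the fixed food contrast.  Because
reporting conventions differ, `vt_definition="with_fixed"` folds in an
as-if-random moment estimate of the food term,
(MS_F − MS_GxF)/(g·r), truncated at zero.  The same quasi-component is
what `variance_percent(include_fixed=True)` uses to print a food
"Var %" next to the random components: a reporting convention with
coherent units, not a true variance component.  The genetic coefficient
of variation is CV = 100·sqrt(V_g)/mean, computed on the raw
measurement scale so that the mean is interpretable.

**Bootstrap CI.**  The default resamples individuals with replacement
within each genotype × food cell (preserving the design) and recomputes
H² per replicate via the EMS route; the CI is the percentile interval
(default 1000 replicates, 95%).  This design choice has a known cost:
conditioning on the realised genotype effects, it captures measurement
replication but *not* the sampling of genotype effects themselves,
which dominates H² uncertainty when genotypes are few.  In simulations
at true H² = 0.5 the within-cell interval covers the truth in roughly
40% of datasets, not 95% — consistent with published clonal-panel
tables in which some intervals exclude their own point estimate.
`unit="genotype"` adds a clustered level (resampling whole genotypes
with replacement), which restores coverage to ≈ 90% in the same
simulations and is the recommended option when the genotype panel is
small.

## BLUPs

Genotype values are predicted as empirical BLUPs,
u_hat = sigma2_G · Z_g' V⁻¹ (y − X beta_hat), with the REML (or EMS)
components plugged into V = sigma2_e I + sigma2_G Z_g Z_g' +
sigma2_GxF Z_gf Z_gf' and beta_hat the GLS fixed-effect estimate.  This
is the exact mixed-model-equations solution, not a balanced-case
shrinkage approximation, so it is valid under unbalanced replication.
Properties relied on downstream: BLUP effects sum to ~0; each |BLUP| is
bounded by the raw genotype-mean deviation (shrinkage); and
sigma2_G = 0 yields all-zero BLUPs.  BLUPs are computed and reported on
the transformed scale where a transform applies, since the PCA and
distance stages consume them directly.

## Transforms

Two variance-stabilising transforms are assigned per trait before
ANOVA: a base-10 logarithm (enzyme activities, maturation age, mean egg
number, day-5 body length) and a rank-based two-step transform
(intermoult duration before maturation).  The log base is a convention
only — F statistics and H² are invariant to it.  The two-step transform
maps fractional ranks (rank − 0.5)/n (mean ranks for ties) through the
standard-normal inverse CDF; this fractional-rank formula is one of
several in use and was chosen because it keeps the extreme ranks
finite; it is isolated in one function and swappable.  Default
assignments are overridable in the pipeline config.

## Growth curves and life history

The von Bertalanffy curve L_t = L_inf(1 − exp(−k(t − t0))) is fitted
per individual by bounded nonlinear least squares
(`scipy.optimize.curve_fit`), multi-started from (i) L_inf slightly
above the observed maximum with k, t0 from the log-linearised
regression and (ii) fixed fallbacks.  Bounds L_inf ∈ (0, 3·max length],
k ∈ (0, 5] stabilise short trajectories.  Trajectories on which no
start converges (e.g. constant length, where k is unidentifiable)
return a flagged fit with NaN parameters rather than raising.  Fits are
per individual — preserving replication for the variance decomposition —
with clone × food summaries taken as means of individual fits.

Recovery behaviour, quantified in the acceptance suite: fits on
noise-free data are exact to 1e-6; with 0.02 mm Gaussian measurement
noise and daily lengths over a 30-day horizon (the duration needed for
six broods at realistic intermoult times) at least 95/100 simulated
individuals recover L_inf and k within 5%.  On a 15-day window the
curve is still far from its asymptote and the sampling noise of k alone
is ≈ 5%, so per-individual 5% recovery is not attainable there; the
estimator remains unbiased (100-seed mean within 5%).

Life-history extraction: maturation age is the first age with a
positive egg count; maturation instar is the number of prior moults
plus one; intermoult durations are mean gaps between moult events
before and after maturation; clutch summaries average the first three
clutches (instar boundaries = adult moults).  Relative tail-spine
length is defined as tail-spine length ÷ body length at the first adult
instar — the named trait has no standard formula, and this ratio is
dimensionless and lies in the magnitude range reported for the panel
(0.10–0.25).

## PCA

The genotype × trait BLUP matrix is standardised per trait, so the
eigendecomposition is of the trait **correlation** matrix (eigenvalues
sum to the trait count; the analysis is invariant to affine rescaling
of any trait).  Loadings are reported as trait–component correlations,
eigenvector × sqrt(eigenvalue) — published loading tables for this
design reach 0.99, which unit-norm eigenvector entries cannot, so the
scaled convention is the one that matches.  Component signs are fixed
deterministically (largest-magnitude loading positive).  Retention uses
the strict Kaiser rule (eigenvalue > 1.0).  With *n* genotypes at most
n − 1 eigenvalues are nonzero; the trailing spectrum is clipped at 0
and the code handles p ≫ n.

## Distances and the Mantel test

Phenotypic distance is the standardised Euclidean distance over BLUPs:
each trait divided by its across-genotype standard deviation, then the
usual Euclidean norm over the chosen trait scope (overall, a category,
or one trait).  At least 3 genotypes are required — with two, the
standardised values collapse to a ± pair and the distance carries no
information.  Genetic distance is the uncorrected p-distance with
pairwise-complete site handling (sites missing in either member are
dropped from that pair's denominator).

The Mantel statistic is the Pearson correlation of lower-triangle
entries; the null jointly permutes rows and columns of one matrix.  For
n ≤ 7 genotypes all n! relabelings are enumerated (identity included),
making p exact — at the five-clone scale this removes Monte-Carlo noise
entirely and the per-test rejection rate at alpha = 0.05 is exactly
6/120.  Larger matrices fall back to seeded random permutations plus
the identity.  The default tail is one-sided positive (do genetic and
phenotypic distances co-vary positively?); 'less' and 'two-sided' are
available.  Ties are handled with a 1e-12 slack so that the identity
permutation always counts.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the clonal common-garden
study: the factorial layout, normal genotype/interaction/residual
effects on stated variance scales, fixed food shifts on trait means in
the published range, von Bertalanffy growth with egg and moult
schedules (maturation age ≈ N(7.6, 1) days, clutches ≈ Poisson(6.2),
juvenile/adult intermoult ≈ 1.9/2.3 days, 30-day horizon covering six
broods), and SNP matrices from mutations dropped on a star or
caterpillar clonal genealogy under an infinite-sites rule, which makes
every pairwise p-distance exactly additive along the genealogy.

It does **not** emulate: non-normal or heavy-tailed residuals,
mortality/dropout (real cells lose individuals; the generator keeps
cells full unless rows are removed), measurement correlation between
traits on the same individual (trait effects are drawn independently,
so cross-trait covariance is zero by construction — pipeline-level PCA
tests therefore exercise machinery, not biology), homoplasy or
back-mutation in the SNPs, and selection or drift.  Passing tests
demonstrate estimator correctness under the model's own assumptions,
not robustness to their violation.

## Numerical choices and problem sizes

* REML optimiser tolerance: scipy L-BFGS-B defaults; ratios bounded in
  [0, 1e8]; all-constant data short-circuits to zero components.
* Degenerate inputs: zero V_T reports H² = 0 with a degenerate (0, 0)
  bootstrap interval; constant trait columns are rejected by name in
  PCA and distance standardisation; constant off-diagonal distance
  matrices are rejected in the Mantel test (r undefined).
* Simulation sizes in the test and acceptance suites were chosen to
  make sampling error small relative to the asserted tolerances:
  heritability recovery uses 200 datasets of 50 genotypes × 2 foods ×
  20 replicates (the 5-genotype design estimates H² with large
  variance; recovery is a property of the estimator, demonstrated where
  the estimator is well-resolved); ANOVA type-I calibration uses 1000
  null datasets at the study's own 5 × 2 × 10 scale; Mantel calibration
  uses 500 pairs of independent random 5 × 5 matrices.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global state.

## Known limitations

* The within-cell bootstrap CI undercovers for small genotype panels
  (see above); the clustered option mitigates but with 5 genotypes any
  resampling-based interval for H² is rough.
* EMS requires a balanced design; the pipeline falls back to REML
  automatically, but then F-tests (which need balanced mean squares)
  are unavailable for that trait.
* The two-way machinery is deliberately not a general n-way ANOVA.
* p-distances are uncorrected by design; no multiple-hit correction or
  tree inference is provided.
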