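# Methods

This note documents the statistical models implemented in `rvscca`, the
defaults and why they were chosen, the numerical decisions, and the
limits of what the synthetic cohorts can demonstrate.

## Study design being modelled

A two-phase case-control imaging-genetics study: subjects are enrolled
by diagnostic group (cognitively normal, mild cognitive impairment,
Alzheimer's disease) in proportions far from the population prevalence
of those states, followed with MRI at months 0, 6, 12, 18 and 24, and
genotyped genome-wide.  Analysis restricts SNPs to autosomal linkage
regions (closed Mb intervals per chromosome band) and asks whether the
minor-allele counts are jointly associated with the rates of structural
brain change, treating the rates — not diagnosis — as the outcome.

## Rates of change (mixed models)

Per ROI *j* the model is a random-intercept / random-slope linear mixed
model in time *t* (months), with fixed group intercept and slope
contrasts (MCI and AD dummies against a CN reference; the dummy coding
is standard 0/1):

    Y_ijt = b0j + b1j MCI + b2j AD + (b3j + b4j MCI + b5j AD) t
            + gamma1_ij + gamma2_ij t + eps_ijt

Estimation is REML with an unstructured 2×2 random-effects covariance
(`statsmodels` MixedLM).  The per-subject endophenotype is
`b3j + b4j MCI + b5j AD + gamma2_ij^`, with the conditional mode
(empirical BLUP) for `gamma2`.  Numerical decisions:

- Fits that fail or do not converge under REML fall back to ML, then to
  a random-intercept-only model; fallbacks and singular fits (slope
  variance at zero) are flagged on the returned fit object and the
  subjects retained.
- When the estimated residual variance is numerically zero (below
  1e-8 of the response variance), the conditional modes are replaced by
  their analytic zero-residual limit — the per-subject OLS fit of the
  fixed-effect residuals.  Optimizers stop slightly short of the
  boundary; the limit is exact there, and this is what makes noiseless
  trajectories recover every subject's slope to machine precision.
- Groups absent from a sample leave all-zero dummy columns; these are
  dropped for fitting and reported as zero coefficients.
- A `method="ols"` alternative skips shrinkage entirely: each subject's
  rate is their own least-squares slope.  It is statistically valid
  (unshrunk BLUP limit), much faster, and is what the repeated-pipeline
  calibration tests use, at small numbers of ROIs, to keep hundreds of
  full-pipeline replicates tractable; single-fit properties are tested
  on the REML path itself.

Predicted random slopes are screened for normality per ROI with a
Shapiro–Wilk statistic and Q-Q data (advisory only).

## Inverse probability weights

With prevalences p_D summing to one and sampled counts n_D, the
standardized weight for group D is w_D = n · p_D / n_D, so that the
per-subject weights sum to the sample size n.  Weights are stored at
full precision; two-decimal values are display-only.  The AD prevalence
helper divides the affected count by the over-55 population and rounds
to the nearest multiple of 0.005, ties away from zero (the convention
chosen where only "nearest half percent" is stated).

## Adjustment for confounding

Ancestry is summarized by classical (Torgerson) MDS of the pairwise IBS
distance matrix D[i,j] = 1 − (1/2m) Σ_k (2 − |g_ik − g_jk|): double-center
−D²/2, take the top d = 10 eigenvectors scaled by √eigenvalue, sign
fixed so the largest-magnitude loading is positive; requesting more
dimensions than the centered Gram rank pads with zero columns and
warns.  The adjustment design is intercept + coordinates + APOE
genotype dummies (reference = most frequent category; constant columns
dropped with a warning).  Genotype counts and rates are residualized
column-wise by weighted OLS; residuals satisfy D'Wr = 0.  For the
sparse CCA the residual columns are standardized to weighted mean 0 /
variance 1, i.e. the cross-correlation scale; standardization happens
after residualization (the alternative order is not exposed because the
cross-correlation of residuals is the quantity the refinement stage
defines).

## Weighted RV test

The weighted cross-covariance uses weighted means and divisor n with
weights pre-standardized to sum to n, so unit weights reduce exactly to
the plain sample covariance.  RV is the squared-covariance ratio given
in the README; it is invariant to separate orthogonal rotations of the
two blocks and reduces to Pearson's r² in the univariate case.

The permutation null permutes Y rows jointly with their weights against
fixed X; p = (1 + #{null ≥ observed}) / (1 + P) (add-one estimator, never
zero).  **Calibration caveat:** when X and Y are residuals on a common
k-column design, both observed blocks lie in the same design-orthogonal
subspace while permuted Y does not, inflating the observed statistic by
roughly n/(n−k) relative to the null draws.  At n in the hundreds with
k ≈ 15 this is a ~2 % distortion, but at pipeline-test scale (n = 60,
k ≈ 7) it mis-calibrates the test badly (measured type-I error 0.2+ at
nominal 0.05).  `rv_permutation_test` therefore accepts the adjustment
design: each permuted Y is re-residualized on it before the RV is
recomputed, using one fixed weight vector — the observed one, which
defines the metric X was orthogonalized in.  With this, measured type-I
error over 200 seeded null cohorts is inside the binomial band around
0.05 and the p-values pass a Kolmogorov–Smirnov uniformity check.

Per-SNP scores on a refined set decompose the RV numerator:
raw_i = Σ_j S²_XiYj, normalized to mean 1 across the set; the sum of raw
scores equals the numerator exactly.

## Sparse CCA and bootstrap importance

The sparse CCA performs alternating soft-thresholded power iteration on
the p×q weighted cross-correlation matrix K: `a ← soft(Kb, λ_u)`,
renormalized; `b ← soft(K'a, λ_v)`, renormalized; initialized at the
leading right singular vector of K; tol 1e-6 on the maximum coefficient
change; max 1000 iterations; sign fixed by the largest-magnitude entry
of a.  λ_v = 0 throughout: a sparse SNP combination against a dense
phenotype combination.  Each half-step solves its subproblem exactly, so
the *penalized* criterion a'Kb − λ_u‖a‖₁ is monotone across iterations
(a'Kb alone is not, and at λ = 0 the fit equals the leading singular
pair).  A fully thresholded coefficient vector is an empty-model result,
flagged rather than raised.

Penalty choice:

- *Cross-validation* (10-fold, grid {0} ∪ {1e-4, 1e-4+5e-4, …, ≤ 0.1})
  maximizes the sum of out-of-fold canonical-variate correlations, ties
  to the smaller penalty.  Under diffuse signal this criterion keeps
  nearly all variables — the known failure mode that motivates the
  alternative below; degenerate folds contribute zero and are logged.
- *Calibration to a selection fraction* bisects λ_u until ≈10 % of SNPs
  have nonzero coefficients (tolerance ±1 %), using the maximum row norm
  of K as the upper bracket (a unit-norm b can never push any
  coefficient past its row norm).  Support size is checked for
  monotonicity as the search proceeds; unreachable targets return the
  nearest achievable penalty with a warning.

Variable importance probabilities: B bootstrap replicates resample
subjects with replacement *within diagnostic group*, recompute the
weighted cross-correlation, refit at the fixed calibrated penalty, and
record the support; VIP_k is the selection frequency, VEP_k = 1 − VIP_k.
Replicates are driven by a single seeded generator; monomorphic columns
in a resample get zero correlation rows and hence zero coefficients;
fully degenerate replicates select nothing and are counted as such.
Bootstrapping resamples the already-adjusted rows (the confounder fit is
not recomputed per replicate; at B in the hundreds of thousands that
recomputation would dominate cost for a second-order correction).
Priority (VIP ≥ 0.5) and top-hit (VIP ≥ 0.9) sets use inclusive
thresholds.  B defaults to 1000 and is a configuration knob; tests use
B = 300–500.

A subtlety the tests document: under a global null the per-replicate
selected fraction sits *above* the full-data calibration target, because
bootstrap duplication shrinks the effective sample size and inflates
resampled correlations (≈2× at n = 80).  Null VIPs are exchangeable
across SNPs with no standouts, which is the property that matters for
ranking.

## Gene-set stage

Genes are closed 1-based bp intervals padded by 20 kb on both sides;
SNP-to-gene assignment is many-to-many.  The gene score is the
second-smallest VEP among its SNPs (robust to long genes accumulating
an extreme minimum); single-SNP genes fall back to their only VEP,
flagged.  Scores map to z-scores via −Φ⁻¹(VEP clipped to
[1/(2B), 1−1/(2B)]), and gene sets are tested with the Efron–Tibshirani
maxmean statistic max(mean z⁺, mean z⁻), restandardized by the mean and
SD of the same statistic over random same-size gene sets (or over the
whole gene universe, behind a flag).  Set p-values come from re-running
the refinement under phenotype permutation via a user-supplied null-VEP
sampler (typically at a scaled-down B), with add-one estimation and
Benjamini–Hochberg adjustment at a deliberately liberal FDR threshold
(0.8) for inclusive candidate screening.  Gene Ontology set definitions
are supplied by the user as a GMT file; none are bundled, as set
contents are release-dependent.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes, from
one integer seed (named child generators split off a `SeedSequence`, so
streams are independent and runs bit-reproducible).

*Genotypes.*  Each SNP's two allele copies are latent standard Gaussians
thresholded at Φ⁻¹(MAF).  SNPs in an LD block share one MAF (as tightly
linked variants do) and an exchangeable latent correlation calibrated —
by root-finding on the bivariate normal orthant probability — so that
the configured ρ *is* the induced allele-indicator correlation.  Raw
latent correlation would be attenuated by the dichotomization (a latent
0.95 yields genotype r² ≈ 0.6); the calibration keeps ρ an interpretable
dial with genotype r² ≈ ρ².  Between blocks, independence.  A latent
ancestry coordinate shifts every SNP's threshold
(allele-frequency stratification) and also shifts ROI baselines, giving
the MDS-adjustment stage a real confounder; APOE ε4 count shifts
baselines as well.  Missingness is completely at random (the only
defensible choice absent a stated mechanism).

*Phenotypes.*  Trajectories follow the mixed model above with group
slopes (CN −0.001, MCI −0.003, AD −0.005 units/month around a baseline
of 2.5 — cortical-thickness-like magnitudes of roughly 0–2 %/year
decline), variance components (0.25², 0.002², 0.05²) for intercept,
slope and noise, and causal SNPs adding `effect_size` (default
0.002 units/month, i.e. one slope-SD) per minor allele to every ROI's
slope — a deliberately simple uniform-pleiotropy pattern.  Visits after
baseline drop out independently with probability 0.1, with baseline and
at least one follow-up always retained.

*Default cohort.*  60 / 90 / 50 subjects (CN / MCI / AD) against
prevalences 0.875 / 0.05 / 0.075 — the oversampling pattern of the
motivating design at roughly one-third scale; 60 SNPs in two labelled
linkage regions; 10 causal; q = 56 ROIs by default, with tests using
q = 4–8 to keep run times in seconds.

What the simulations do *not* emulate, and hence what passing tests do
not establish for real data: realistic genome-wide LD and allele
frequency spectra, haplotype-level ancestry structure, ROI-specific and
sign-heterogeneous genetic effects, informative dropout, diagnosis
misclassification, and scanner/site effects.  The tests establish the
*statistical mechanics* — calibration, recovery, monotonicity,
equivalences — not clinical effect sizes.

Two test-design choices worth stating: the causal-vs-null VIP separation
property is evaluated on a cohort with *unlinked* SNPs, because a "null"
SNP in an LD block with a causal one genuinely carries association and
the causal/null dichotomy is ill-posed under LD; and repeated-pipeline
calibration checks use the OLS rate path (see above) with problem sizes
n = 60, p = 8, q = 4 over 200 replicates and 99 permutations each.

## Known limitations

- The RV permutation test without the design-aware option is
  anti-conservative whenever k/n is non-negligible; pass the design.
- `MixedLM` occasionally lands on variance-component boundaries; the
  fallback chain is deterministic but fallback fits have slightly
  different shrinkage than a converged REML fit.
- The penalty calibration assumes support size decreases in λ_u along
  the bisection path; plateaus (heavily tied correlation structure) end
  at the nearest achievable fraction with a warning.
- Gene-set restandardization against random same-size sets is exact only
  in expectation; with very few genes the reference SD is noisy (the
  whole-universe set is rejected as degenerate).
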