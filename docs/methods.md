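# Methods

This note records the statistical model behind each stage, the defaults
and why they hold, what the synthetic generator does and does not
emulate, and the judgment calls made where the design was genuinely open.

## Signature derivation

Per-probe two-sample comparison (cell population vs skin reference, or
cytokine-treated vs untreated keratinocytes) uses a moderated t-statistic
with empirical-Bayes variance shrinkage. With pooled sample variance
`s²` on `d` residual degrees of freedom and a scaled-inverse-χ² prior
`(d0, s0²)`,

    s²_post = (d0·s0² + d·s²) / (d0 + d)
    t_mod   = log2FC / sqrt(s²_post (1/n_a + 1/n_b)),  df = d0 + d.

`(d0, s0²)` are estimated by moment matching on the log sample variances
(digamma/trigamma moments; trigamma inverted by Newton iteration). When
the observed log-variances show no extra-sampling spread the estimate is
`d0 = ∞` and the statistic becomes z-like; `d0 = 0` recovers the ordinary
equal-variance t-test. Both limits are asserted in tests, and the
estimator was verified during development to agree with the reference R
implementation of this shrinkage to machine precision on heteroskedastic
instances.

Selection is a strict two-step ranking: (1) keep probes whose mean is
higher in the population (lower, for "repressed"); (2) retain the
`pool = 2000` smallest p-values; (3) of those, keep the `size = 1000`
largest fold-changes (most negative, for "repressed"). Fold-change is the
difference of log2 means. Ties at either boundary break by smaller
p-value then lexicographic probe id, so derivation is deterministic.
Zero-variance probes with zero fold-change get p = 1; the direction
filter drops them from signatures.

## Profile scoring

Subjects must form exact PP/PN pairs; the per-probe difference is
PP − PN after an optional per-probe least-squares removal of additive sex
and batch effects (grand mean restored; a single-sample batch level drops
the batch term with a warning). Ties (difference exactly 0) count in
neither direction — the ratio is defined over elevated/decreased probes
only.

The Fisher 2×2 table is {signature, rest of array} × {up, down}, ties
excluded; the array-wide background is a deliberate choice the source
method leaves unstated — it keeps margins well defined and matches the
"fraction elevated vs array behavior" reading. The reported ratio applies
a Haldane +0.5 to both counts only when one count is zero; test
statistics always use raw counts. The Wald interval uses z = 1.96 fixed
(the exact 0.975 quantile changes nothing at one-decimal percent
rounding, and 1.96 is what readers expect to see).

Dual criterion: (1) Holm across all populations on the one-sided Fisher
p-values; (2) populations ranked per subject by descending raw ratio,
each signature re-tested after removing probes belonging to any
higher-ranked signature, and the filtered p-values Holm-adjusted within
the same family (a config flag switches criterion 2 to raw p-values; the
original procedure does not say, and Holm is the conservative default).
An emptied criterion-2 subset fails the flag with the reason recorded.
The per-subject ranking (rather than cohort-wide) is likewise an
assumption, switchable in code.

Category display uses the grand-mean rule: R* = mean of member
populations' mean ratios; the representative is the max-ratio member when
R* > 1, else the min-ratio member, ties lexicographic.

## Cytokine calls

Same counts and ratio over each cytokine-responsive set, but the Fisher
test is two-sided (bias either way is a call) and the family for
Benjamini–Hochberg FDR is the set of cytokine signatures within one
subject — calls are per-subject readouts. A call additionally requires
ratio > 3/2 (up) or < 2/3 (down); both thresholds live as exact
`Fraction`s compared against raw counts, which makes the mirror property
(negating all differences swaps up- and down-bias exactly) an identity
rather than a floating-point accident.

## Stratification

Scores are log2 ratios standardized per signature (mean 0, sd 1, ddof 1;
a constant column is an error naming the signature). Subject clustering:
complete-linkage agglomeration on Euclidean distance (average linkage and
Manhattan distance available; the replication analysis in the source used
average linkage). Cutting at k uses the maxclust criterion; cuts of one
tree are nested. Cluster ids are relabeled by descending mean of the
standardized row sums, so tier names (strong/moderate/weak,
IL-13-strong/IL-13-weak) are stable and meaningful. k is fixed at 3 and
2 by default — the subgroup counts were externally replicated, not chosen
by an internal criterion — and both are CLI parameters.

Per-feature average silhouette widths use the 1-D distance |xᵢ − xⱼ|
within each signature column; members of singleton clusters score 0 by
the usual convention.

Risk-locus clustering uses complete linkage on Manhattan distance between
allele-count columns, pairwise-complete over missing genotypes with each
pair's sum rescaled by n_subjects/n_complete so loci with different
missingness remain comparable; an all-missing locus is excluded with a
warning.

## Outlier screening

The score matrix is centered and reduced by SVD to two principal axes
(rank-1 data is legal: the second axis then carries zero variance — the
"error on rank < 2" alternative would contradict the one-axis use case).
Each axis gets a single, non-iterated Grubbs test:

    G = max|xᵢ − x̄| / s,   t* = sqrt(n(n−2)G² / ((n−1)² − nG²)),
    p = min(1, 2n·P(T₍n−2₎ > t*)).

Only if either axis has p < α does the bivariate step run: minimum
covariance determinant with support fraction 0.75, flagging squared
robust Mahalanobis distances above χ²₂(0.975) = 7.378. The fixed quantile
is reproducible; the adaptive-quantile refinement of the robust-distance
literature is deliberately not the default. A numerically constant PC
cloud (total variance < 1e-12) returns no flags instead of fitting a
degenerate MCD. Under the null the per-cohort flag probability runs
slightly above α because MCD distances are inflated in small samples;
the gate keeps the practical rate low and the calibration test tracks the
Grubbs component directly.

## Association scan

For every (cell-type, cytokine-set) pair, shared probes are removed from
both sets before any score is computed; the per-subject score correlated
is the proportion of the remaining probes PP-elevated (monotone in the
ratio, bounded, and tie-friendly under ranks). Spearman uses midranks;
p-values come from the t approximation `t = r√((n−2)/(1−r²))`, replaced
by the exact permutation distribution (full enumeration) for n ≤ 9. The
result table always has |cell sets| × |cytokine sets| rows; a pair
emptied by overlap removal is reported with `r_s = NA` and a reason. Raw
P < 0.05 is the headline column, with BH-adjusted values alongside.

## Genetics

Cliff's delta Δ = (#{x>y} − #{x<y})/(n_x n_y) is computed by direct
pair counting; its p-value uses Mann–Whitney machinery — exact
enumeration when n_x·n_y ≤ 400 *and* the data are tie-free, otherwise
the tie-corrected normal approximation (allele counts are heavily tied,
so the exact path effectively serves small tie-free score comparisons).

The cumulative risk score is 100 × the predicted case probability from an
intercept-bearing maximum-likelihood logistic regression of case status
on per-locus allele burden (0/1/2) in a training cohort; coefficients
beyond |15| or non-finite fits are treated as separation and the fit
aborts with advice to use the L2-penalized fallback. Missing cohort
genotypes are imputed with the per-locus mode (smallest count on ties);
subjects untyped at more than 15 loci get no score. Group comparisons
report the rank-sum test (exact when small and tie-free, else
tie-corrected normal with continuity) and Welch's t — the unequal-variance
form, since nothing guarantees equal spread between tiers. The
treatment-history screen is Welch per (treatment, signature) cell with BH
across the whole table; degenerate cells are NA.

## Synthetic worlds

The generator states a world and the tests live in it:

- Probe baselines ~ Normal(8, 2²) log2 units — a typical normalized-array
  dynamic range — with i.i.d. Gaussian noise, sd 0.5.
- Reference panels: 4 replicates per population, 21 skin-reference
  samples, planted markers +2.0 log2 in their population.
- Cohorts: default 62 subjects split 23/24/15 (largest-remainder
  apportionment of the published tier proportions) and 31/31 across
  cytokine tiers; planted cell modules shift PP by base_effect × tier
  scale (1.0/0.6/0.2), cytokine modules by ±1.0 (induced/repressed) times
  the cytokine tier scale (+1.0 strong, −0.5 weak — the weak tier
  suppresses induced and elevates repressed transcripts, reproducing the
  opposing-signature pattern). A planted shift δ makes a probe
  PP-elevated with probability Φ(δ/(0.5√2)), which the tests use as a
  closed-form oracle.
- Cytokine sets overlap cell modules by 10% of their probes by default to
  exercise the scan's overlap removal.
- Genotypes: baseline risk-allele frequencies ~ Uniform(0.2, 0.5),
  Binomial(2, f) counts, 2% missingness; planted (locus, tier, δ) shifts
  move f for that tier's subjects. The training set defaults to 2568
  cases / 2525 controls (scalable); case genotypes are exponentially
  tilted by a per-locus log odds ratio (0.25 by default), which is
  exactly the retrospective sampling a prospective logistic model
  implies, so refits recover the coefficients.

Not emulated: probe-level array chemistry, normalization artifacts,
probe–probe correlation (a block-correlation knob exists but defaults
off), within-subject PP/PN correlation beyond the shared baseline, and
linkage disequilibrium between loci. A green recovery test therefore
establishes that the pipeline finds the planted structure under marginal
Gaussian noise — not that it would survive correlated noise or platform
effects.

## Numerical conventions

- Seeds: every generator takes an explicit seed; the pipeline derives
  per-stage seeds from the run seed by hashing, all below 2³¹.
- Determinism: sorts are stable merges with documented tie-breaks; two
  runs with the same config and seed produce byte-identical artifacts
  (asserted via manifest checksums).
- Holm/BH come from statsmodels; Fisher from scipy — both are
  cross-checked in tests against hand-rolled definitions and exact
  combinatorial tail sums.
- The scaled-down test profile (12 subjects, 4000 probes, size-200
  signatures) exists purely to keep CI fast; defaults are the full
  62-subject world.

## Known limitations

- The dual criterion's second test family and its adjustment are
  assumptions (documented above) since the original text does not fix
  them; both switches are exposed.
- The null flag rate of the MCD step exceeds its nominal quantile at
  n ≈ 62; the Grubbs gate mitigates but does not remove this.
- Exact Mann–Whitney p-values are unavailable under ties; allele-count
  comparisons always use the asymptotic form.
- The association scan reports raw-P significance as the headline number;
  with 1312 pairs this is a screening readout, not a confirmatory one.
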