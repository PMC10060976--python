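# Methods

This note documents the models, algorithmic conventions and design
choices behind `chemonet`, and what the synthetic-data tests do and do
not establish about real cohorts.

## The synthetic study design

`chemonet.synthetic.SimulationDesign` defines the study conditions; all
cohorts of one design share gene baselines and planted effects and
differ only by a per-cohort baseline offset, so cross-cohort model
transfer is a meaningful test. Expression for gene *g* in tumor sample
*i* of one cohort is

    x_gi = mu_g + c_g + e_g + z_i * b_g + eps,   eps ~ N(0, sigma^2)

with `mu_g ~ N(6, 1)` a fixed per-gene baseline (log₂ scale), `c_g ~
N(0, 0.5^2)` the cohort offset, `z_i ~ Bernoulli(pi)` the latent cluster
(high/low), `b_g` the planted high-vs-low log₂ effect and `e_g` the
tumor-vs-normal enrichment (chemokine panel only). Donor-matched normals
share the donor's baseline and carry neither `e_g` nor the cluster term.

Defaults (units, and why):

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 200 | tumors per cohort; the scale of the mid-size real cohorts |
| `n_cohorts` | 2 | training plus one sibling test cohort |
| `n_genes` | 300 | 8 panel + 40 IFN/exhaustion + 40 OXPHOS/TCA/FAO + 10 TRP + null filler |
| `cluster_prevalence` | 0.5 | balanced clusters (observed cluster sizes are roughly comparable) |
| `panel_shift` | 2.0 log₂ | high-vs-low separation of the 8 panel genes |
| `module_shifts` | +1 (IFN/exh., TRP), −1 (OXPHOS/TCA/FAO) log₂ | co-regulated programs of the high cluster |
| `tumor_enrichment` | 2.0 log₂ | four-fold panel enrichment of tumor over normal, beyond the cluster term |
| `paired_fraction` | 0.5 | donors with a matched normal sample |
| `infiltration_link` | 1.0 | logistic slope of the CD8 score on centered mean panel expression |
| `infiltration_noise` | 0.1 | additive noise of the CD8 score; with the slope it yields ρ(CXCL9, CD8) ≈ 0.7 |
| `noise_sd` | 1.0 log₂ | residual expression noise |
| `baseline_hazard` | ln2/1825 d⁻¹ | ≈ 5-year median overall survival |
| `cluster_log_hr` | 0.0 | null survival effect by default — the design's headline negative finding |
| `censoring_rate` | 0.4 | uniform censoring tuned numerically to this expected fraction |

Because the cluster term is not centered, the population tumor-vs-normal
contrast of a panel gene is `e_g + pi * b_g` (3 log₂ at defaults) while a
design with `panel_shift = 0` isolates `e_g` exactly; the screen's
four-fold gate therefore has planted true positives comfortably above
threshold rather than sitting on it.

The toy metabolic model has 16 GPR-bearing reactions in four subsystems
(OXPHOS, citric acid cycle, fatty acid oxidation, tryptophan metabolism)
over the planted metabolic genes, one control reaction on null genes and
one reaction without a rule. Its true regulation is the exact GPR
evaluation of the planted linear fold changes, so Monte-Carlo estimates
have an analytic target.

What the generator does **not** emulate: negative-binomial count noise
and library-size effects, batch structure beyond cohort mean offsets,
gene-gene correlation within modules beyond the shared cluster factor,
informative censoring, or realistic cell-type deconvolution. Passing
tests therefore establish correctness and calibration of the statistics
under a Gaussian log-expression model with planted effects — not
robustness to every artefact of real RNA-seq/microarray cohorts.

## Preprocessing conventions

Raw values are transformed as log₂(x+1); multi-probe genes are collapsed
by geometric mean on the linear scale before the log transform (a zero
probe yields a zero geometric mean, documented, not an error). Gene
symbols are matched case-insensitively after trimming; collisions after
case-folding are errors. "Normalized" panel expression for clustering is
the per-gene z-score computed **within each cohort**; whether to z-score
within cohort or pooled is genuinely open, and within-cohort scaling was
chosen because it removes platform/location effects so that medoids
transfer across cohorts. Missing clinical fields stay missing.

## Screening

Paired *t* statistics use the sample SD of the differences (n−1), with
Cohen's d = mean(d)/sd(d). Spearman p-values use the t approximation
(adequate at the intended n of hundreds). FDR families are per question
within a cohort: all candidate genes of one screen are corrected
together. The four-fold rule is applied to the *mean* log₂ difference
(≥ 2), consistent with the t-test estimand, not to the median. The
correlation network keeps gene–gene and gene–cell-type edges with
|ρ| > 0.4 (signed ρ reported); cell-type–cell-type pairs are not part of
the network.

## Clustering

PAM minimises the total cosine distance of samples to their medoid.
Small instances are solved exactly — k = 2 by a vectorised scan of all
medoid pairs (up to n = 600), any k with at most 20 000 candidate subsets
by enumeration — because single-start BUILD+SWAP provably sticks in
local optima on a noticeable fraction of small instances; larger
problems use BUILD+SWAP with lowest-index tie-breaks, making every fit
deterministic irrespective of seed. The cluster whose members have the
greater mean scaled panel expression is named "high"; the rule is
invariant to sample order.

Diagnostics: WSS is the sum of squared cosine distances to the medoid;
mean silhouette uses the precomputed cosine distances with the
convention that singleton clusters score 0; the recommended k is the
silhouette peak (the WSS bend is reported, not auto-decided). Explained
variance is the Euclidean 1 − WSS/TSS on the scaled matrix even though
the clustering distance is cosine, because the between/total sum-of-
squares decomposition only exists for squared Euclidean distance.
Cross-validation refits PAM on each training 9/10, assigns the held-out
tenth to the nearest medoid and reports the mean adjusted Rand index
against the full-data labels, with folds shuffled by the seed.

Projection z-scores the test cohort with its **own** per-gene mean/SD by
default (cross-platform transfer; training parameters available behind a
flag), then classifies each test sample by the inverse-distance-weighted
vote of its 15 nearest training samples under cosine distance. A
zero-distance neighbor's label is copied directly; exact weight ties
resolve to the smallest-index neighbor among the tied clusters — a
documented deterministic rule.

## Profiling

Differential expression uses Welch's unequal-variance t-test (robust to
unequal cluster sizes, which the clusters generally have); "regulated"
means FDR < 0.05 and linear fold > 1.25 or < 1/1.25, evaluated from the
log₂ mean difference. The (mean_diff, se) pair of this table is the
exact input contract of the metabolic step.

ssGSEA ranks each sample's genes by decreasing expression (stable
tie-break by gene order), weights in-set steps by rank^α with α = 0.25,
and sums the running difference between the in-set and out-of-set
cumulative distributions; the optional normalisation divides the whole
score matrix by its range. α and the normalisation are configurable and
recorded on the result object, since ssGSEA variants differ in both.
Note a compositional property of rank-based scores: when many genes
truly shift between groups, the score of a "null" set also shifts;
specificity statements therefore use permuted labels, not null sets.

## Metabolic regulation

The GPR grammar is `expr := term ('or' term)*; term := factor ('and'
factor)*; factor := GENE | '(' expr ')'` with case-insensitive keywords
and `and` binding tighter than `or`; associative chains are flattened at
parse time so print → parse round-trips to the identical tree. The
activity algebra — AND → min, OR → sum — is the standard
expression-to-flux mapping convention; regulation is defined as the
ratio of the rule evaluated at fold activities 2^δ to the all-ones
baseline, which guarantees exact neutrality (zero effects ⇒ zero
regulation) and makes the estimator unbiased under no change.

One δ matrix of shape genes × draws is drawn per run, so reactions
sharing genes co-vary across draws, and the computation is halved. The
p-value is the two-sided empirical sign rule with a +1 pseudo-count,
p = min(1, 2(min(#{reg ≤ 0}, #{reg ≥ 0}) + 1)/(n + 1)); with n = 1000
draws its floor is ≈ 0.002. Genes without a differential-expression
estimate default to neutral (0, 0) with a logged warning; a strict mode
raises instead. Activities 2^δ are strictly positive, so the log₂ ratio
is always defined. These conventions (algebra and p-value construction)
are this package's own documented choices among the plausible variants.

## Survival

The Peto-Peto test weights the log-rank increments by the modified
pooled survivor estimate S̃(t_j) = Π_{t_i ≤ t_j} (1 − d_i/(n_i+1)); an
internal flag forces unit weights, reducing it to the standard log-rank
statistic for oracle checks. Uni-variable Cox fits report the linear
hazard ratio from the linear-only model — the spline columns are
strongly collinear with the covariate, so the linear coefficient of the
joint model is not usefully identified — and the non-linearity p-value
from the likelihood-ratio test of the natural-cubic-spline terms
(df = 3: knots at quantiles, two non-linear basis columns) against the
linear model. Non-convergence flags the result instead of raising.

Ridge Cox standardises covariates internally, drops zero-variance
columns with a warning, and picks the penalty by maximising the
cross-validated partial log-likelihood over a grid, folds stratified by
event status. Harrell's C counts tied scores as 0.5 and is
scale-invariant — consequently the "infinite-penalty" limit attains
C = 0.5 only at exactly zero coefficients; for any finite penalty the
tiny coefficients retain the unpenalised direction's ordering. The
add-on value of expression is the concordance difference of the
clinical+expression and clinical-only models on an independent
validation cohort.

## Problem sizes and numerical choices

The evaluation battery (`chemonet.evaluation`, shared by the tests and
`scripts/acceptance.py`) uses: 20 simulated studies for cluster recovery
and for screening; 30 replicates × 17 reactions (= 510
reaction-replicates) at 1000 draws for CI calibration; 2000 null
replicates (100 per arm) for the Peto-Peto type-I error; 20 replicates
of n = 500 for Cox hazard-ratio recovery; training and validation
cohorts of n = 400 for the ridge concordance comparison; and 200
end-to-end replicates (n = 120, 110 genes) for the null-survival mirror.
These sizes give Monte-Carlo errors comfortably below the property
margins being checked while keeping the battery at about a minute.

Tolerances: exact equality is asserted wherever the computation is
deterministic (GPR algebra, BH step-up, PAM cost on exactly solved
instances); 1e−9 for the ssGSEA oracle; 1e−6 for the SE→0 Monte-Carlo
limit. Ties: ranking and neighbor ties break by stable order; PAM ties
by lowest index. Degenerate inputs (constant genes, zero vectors, empty
groups, zero marginals, all-censored data) raise informative errors
rather than propagating NaNs, except where a warning is the documented
behaviour (no events in Kaplan-Meier; zero geometric mean).

## Known limitations

- The GPR activity algebra and the Monte-Carlo p-value are conventions,
  not estimates of any particular third-party implementation's behaviour.
- ssGSEA normalisation variants differ across tools; only the documented
  variant is implemented.
- The Cox spline non-linearity test uses unpenalised spline terms with
  fixed df; penalised smoothing is out of scope.
- The generator's Gaussian log-expression model understates the
  heavy-tailed noise of real counts; operating characteristics on real
  cohorts may be less favourable than the synthetic ones reported here.
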