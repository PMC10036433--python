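# Methods

## The per-gene joint regression model

For gene *j* with standardized muscle expression x_m, IMAT expression x_i
and standardized responses y_g (GIR) and y_f (FG), the model is

    [y_g  y_f] = [x_m  x_i] B + E,        B = [[β_mg, β_mf], [β_ig, β_if]]

fitted by least squares, which coincides with the Gaussian maximum
likelihood estimate under an unrestricted 2 × 2 residual covariance.
Because the two responses share the same predictors, the joint estimate
equals two independent single-response fits entrywise — this theorem is the
basis of the oracle test in the suite. Every variable is z-scored with the
population SD and the model carries no intercept: β values are then
comparable across genes, which the clustering stage requires. Gene scoring
is the likelihood ratio of the full model against the intercept-only null:

    score = ℓ_full − ℓ_null = (n/2) · ln(det S₀ / det S₁) ≥ 0,

with S₀ = YᵀY/n and S₁ the ML residual covariance. A numerically exact fit
(det S₁ = 0) is reported as an infinite score rather than an error; a
singular S₀ (collinear responses) is a degenerate input. Predictor
collinearity is guarded by the condition number of the 2 × 2 Gram matrix
(limit 10⁸); beyond it the fit aborts naming the gene instead of silently
pseudo-inverting. Ranking ties are broken by gene id, making selection
deterministic.

## Gene clustering and pattern tags

The default feature space is the 4-vector of fitted coefficients —
clusters are then directly interpretable as tissue–phenotype sign patterns;
concatenated z-scored expression across both tissues is available as an
alternative. k-means uses 50 restarts and a fixed seed; hierarchical
clustering uses Euclidean distance with average linkage cut at k. Labels
are renumbered by descending mean member score, so the labelling does not
depend on input order. Each cluster is tagged with the nearest of three
canonical patterns — (+,−,+,−), (+,−,−,+), (−,+,0,0) for
(β_mg, β_mf, β_ig, β_if) — where entries below a quarter of the largest
mean-|β| count as zero and a zero/nonzero mismatch costs half a sign match.

## Participant networks and classification scores

Networks are directed: kNN is asymmetric, and out-neighbours are the only
reading under which "each participant's direct neighbours" defines a score
for every node. Genes are z-scored before distance computation so no single
high-variance gene dominates the Euclidean metric. Distance ties break by
participant id. With k = 3 and binary labels the raw score is 2/3 or 1;
averaged levels combine class *fractions* (not hard votes) and call a class
only on a strict majority (> 0.5), otherwise "ambiguous". A participant is
non-unique in a tissue when its three cluster-level calls disagree, and
discordant when the averaged call differs from the clinical label.

## Intervention stage

Relative change is Δ% = 100·(post−pre)/pre. Clinical change uses the
classical paired *t* (df = n−1); all-zero differences return t = 0, p = 1,
and zero-variance nonzero differences raise an infinite-statistic error
rather than returning ±inf. Relative quantification follows ΔΔCt:
ΔCt = Ct_target − Ct_ref (*TBP*), ΔΔCt against a calibrator, reported level
log₂ 2^−ΔΔCt = −ΔΔCt. The calibrator defaults to the per-gene mean
pre-intervention ΔCt (a named calibrator sample is available); levels are
invariant to any per-sample Ct shift by construction. Differential
expression uses one-way two-group ANOVA (identical to the squared unpaired
t), tolerating unpaired groups after sample dropout; a paired alternative
exists but is off by default. The screen computes Pearson r (Spearman via
config) for each (gene, clinical variable) on pairwise-complete data,
flags significance per test at α = 0.05 unadjusted — matching apparent
per-test flagging conventions in small-panel validation studies — and
always reports Benjamini–Hochberg q-values alongside so the multiplicity
cost is visible. Cells with fewer than 3 complete pairs are reported
missing, never computed.

## The synthetic-data generator

**What it emulates.** A cross-sectional cohort of 16 participants
(10 obesity / 6 type 2 diabetes) whose clinical variables are drawn
per group from Normal(mean, SEM·√n) using the printed demographics tables;
a longitudinal cohort of 17 participants with pre/post values drawn from a
bivariate normal with within-participant correlation ρ (default 0.8 —
plausible tracking for anthropometric variables; the source tables print
no value, so it is an exposed parameter); and a qPCR panel of the 15
candidate genes plus *TBP*.

**Positivity and calibration.** All clinical draws are truncated to
positive values by resampling. Plain truncation inflates the mean of
high-coefficient-of-variation variables (for the obesity-group insulin
distribution the inflation is ≈ +7 pmol/l), so the pre-truncation location
is solved such that the truncated mean equals the printed mean — by Brent
root-finding on the univariate hazard formula, and for paired pre/post
draws by fixed-point iteration on the closed-form first moments of the
quadrant-truncated bivariate normal. Calibration is verified by the
acceptance suite: grand means over 1500 replicate cohorts match every
printed cell of both tables within 3 Monte-Carlo SE.

**Planted expression structure.** A latent health score h per participant
is the standardized first principal direction of (z(GIR), −z(FG)) — high
for insulin-sensitive, normoglycaemic individuals. A signal gene with
template loadings (w_m, w_i) has expression w_t·h + N(0, σ) in tissue t;
the three templates are (+1,+1), (+1,−1), (−1,0) with 14/23/22 genes by
default plus 500 pure-noise genes. The default noise σ = 0.3·|w| gives
realistic single-gene effect sizes (|r| ≈ 0.7–0.9 with the phenotypes at
n = 16). Clinical variables are drawn independently per variable (no
covariance is printed); group separation alone induces the GIR–FG
anticorrelation at cohort level. The generator can mark participants as
"mislabeled": their expression is generated from the opposite group's mean
latent score, which the classifier should flag as discordant.

**What it does not emulate, and what passing tests show.** No probe-level
microarray structure, no RNA-quality artefacts, no gene–gene correlation
beyond the shared latent score, and no physiological model of the
intervention itself: the pre/post draws are distribution-calibrated, not
mechanistic. Recovery results on these cohorts therefore demonstrate the
pipeline's correctness and statistical behaviour under its own modelling
assumptions — not performance on real transcriptomes, where correlated
nuisance structure would lower effective signal-to-noise.

## Numerical and design choices

- **Two behaviours of the planted design worth knowing.** (1) At very low
  expression noise, a template with both tissue loadings nonzero makes x_m
  and x_i nearly collinear; the fitted β then smears along the
  (muscle, −IMAT) split direction even though their sum is stable. Sign
  recovery is therefore assessed on the entrywise *median* β across a
  template's member genes, and exact cluster recovery is benchmarked on
  groups planted directly in β space; "noiseless-limit" checks use small
  nonzero noise so the collinearity guard does not trigger. (2) Under the
  printed-table calibration the two groups genuinely overlap in the latent
  score (the published obesity GIR range overlaps the diabetic range), so
  expression-based classification cannot reach perfect concordance no
  matter how clean the expression is — the measured ceiling is ≈ 87%, and
  a few discordant participants per cohort are the expected, realistic
  behaviour. Concordance ≥ 90% is verified on well-separated cohorts
  (printed means, within-group SEMs scaled by 0.25).
- Seeds: one root integer; per-stage child seeds derived via
  `numpy.random.SeedSequence`, so any stage reruns bit-identically in
  isolation. Manifest checksums cover data files only (provenance sidecars
  carry timestamps).
- Missing values: analyses drop affected participants pairwise and log the
  count; readers treat empty cells as missing.
- Default sizes everywhere follow the study design (n = 16 and 17; 59
  signal + 500 null genes; top-59 selection; k = 3 clusters; k = 3
  neighbours). Monte-Carlo checks in the test suite use 20–1500 replicates
  depending on the statistic's variance.

## Known limitations

- The likelihood-ratio reading of the gene score is one documented choice;
  the clustering method (k-means vs hierarchical) is configurable because
  both appear in the source analyses, with k-means the default.
- Pearson is the default screen statistic; with n = 17 a single outlying
  participant can dominate r, and the Spearman option is the robust check.
- The ANOVA for pre/post expression ignores pairing by design (dropout
  leaves the groups partially unpaired); the paired option trades samples
  for power when pairing is complete.
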