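# Methods

`pdig` implements a quantitative-trait imaging-genetics analysis of
Parkinson's disease (PD) on the cortico-basal ganglia-thalamocortical
(CBGT) circuit, together with a synthetic-cohort generator that stands in
for the restricted clinical database the design is modeled on.  This note
records the model, the defaults and why, the numerical choices, and what
the synthetic validation does and does not establish.

## The analysis

**Intermediate phenotypes.** Genetic association in small cohorts gains
power by testing heritable, disease-correlated quantitative traits rather
than case/control status.  Here the traits are (a) node degree
centralities of an 8-region structural network — caudate, putamen,
pallidum, thalamus, motor/sensorimotor cortex, associative cortex, limbic
cortex, substantia nigra — and (b) the MDS-UPDRS clinical severity score.

**Connectivity.** For regions *i*, *j* with surface areas S_i, S_j and
streamlines *f* of length l(f), the edge weight is the fiber density

    w(i,j) = meanFA(i,j) · [2/(S_i+S_j)] · Σ_f 1/l(f),

the streamline count normalized by length and surface area and modulated
by mean fractional anisotropy along the connection.  Degree centrality
(DC) of a node is the sum of its incident edge weights.  The formula is
isolated in `connectome.fiber_density_edge` and its variant identifier is
recorded in every pipeline manifest, because length/area normalizations
vary across the connection-efficiency literature; swapping the variant
touches one function.  Mean FA is the mean over fiber-level FA summaries
of the pair (pooling all FA samples along fibers would be an alternative;
fiber-level summaries are what the streamline tables carry).

**Group contrast.** Per-node two-sample Welch t-tests (HC vs PD) with
Bonferroni correction over the 8 nodes (m = 8).  Testing is at the node
(DC) level, not the 28 edges; edge-level testing is a documented
extension.  Welch rather than pooled-variance is the default because
group variances are not assumed equal; the choice matters little at equal
group sizes.

**Association.** Each candidate SNP is coded additively (0/1/2 copies of
the minor allele) and each phenotype is regressed on
[1, SNP, age, sex] by OLS.  Significance uses the SNP coefficient's |t|
against a permutation null: the phenotype vector is permuted across
subjects (the standard quantitative-trait null under exchangeability),
the full model is refit per permutation, and the empirical p is the
add-one estimate (1 + #{|t*| ≥ |t|})/(1 + N) with N = 10,000 by default —
never zero, bounded below by 1/(N+1).  Two-sided throughout; covariates
are refit inside each permutation.  A flag permutes genotype labels
instead for sensitivity analysis.  Missing calls are dropped per SNP
(complete-case); sex is coded F = 0, M = 1.  Each (phenotype, SNP) pair
draws its own substream from the master seed after subjects are sorted by
id, so results are exactly invariant to input row order.

**Models.** Three MDS-UPDRS regressions: A (imaging DC features), B (SNP
features), C (both), each plus covariates (family history, MoCA, GDS,
sex, age, site) and two-way interactions among candidate predictors.
Selection is backward elimination under the overall-model-p rule: a term
is removed when its removal strictly lowers the p-value of the model's
overall F test, iterated to a fixed point, ties broken by term order.
This rule (rather than AIC/BIC or partial-F thresholds) is the procedure
being studied; it is deliberately not replaced.  No main-effect hierarchy
is enforced — an interaction may outlive its parents, as the rule itself
imposes none.  Explained variance is decomposed by sequential (Type-I)
sums of squares in retained-term order, with F per term against the final
model's residual mean square; per-term "percent explained" is
100·SS/SS_total, so the column sums to 100·R² exactly — the identity that
makes a printed per-term table reconcile with the model's R².  The
multi-center covariate enters as reference-coded indicators that travel
as a single term (one removal decision, pooled SS).

**Validation.** Leave-one-out cross-validation with the term set fixed
(selected once on the full data) and coefficients refit per fold; RMSE
and Pearson r between predicted and actual scores.  Fixing the term set
mirrors a single-model validation design and is optimistic relative to
reselecting per fold; `loocv_predict` takes any term set, so the stricter
variant is a one-line change.  Per-fold refits are checked against the
closed-form identity ŷ₋ᵢ = yᵢ − eᵢ/(1 − hᵢᵢ) in the tests.

**Genotype QC.** SNPs are excluded when folded MAF < 1%, exact
Hardy-Weinberg p < 10⁻⁶, or missing-call rate > 5%.  The HWE test is the
exact conditional test (Wigginton-style recurrence over heterozygote
counts, two-sided by probability ordering) rather than chi-square, which
is unreliable near the MAF filter boundary.  Per-criterion exclusion
counts are reported marginally (a SNP failing two filters increments
both) with the union removed once; the convention is stated in the report
because sequential and marginal counts differ.  The minor allele is
determined empirically after missingness, ties at 0.5 keeping the
declared coding.  Subject-level call rates are computed and reported but
not used for exclusion by default (no defensible threshold to hard-code).
Population structure is assessed by identity-by-state distance
(1 − mean shared-allele fraction over jointly observed SNPs) and
classical (Torgerson) MDS; negative eigenvalues of the double-centered
Gram matrix — possible when missingness makes the input non-Euclidean —
are dropped from coordinates and reported.

## The synthetic cohort

The generator produces the study conditions end to end with known ground
truth; all defaults below are fixed design choices, not fitted values.

- **Subjects.** 40 HC + 40 PD.  Age ~ Normal(62, 9) years in both groups
  and sex exactly balanced within group — the groups are *matched by
  construction*, which is what downstream tests rely on; absolute values
  are typical of a PD cohort.  GDS is an integer draw over 0-15
  (Binomial(15, 0.15)), MoCA over 20-30 (20 + Binomial(10, 0.7)),
  identical between groups; handedness 90% right; family history 10% (HC)
  / 30% (PD); site uniform over 9 centers.
- **Genotypes.** 7 PD-linked candidate SNPs (PARK2 ×3, PARK7, SNCA,
  HtrA2, GIGYF2) at MAFs 0.25-0.35 plus 5 background SNPs.  Genotypes
  follow Hardy-Weinberg proportions at the target MAF; a Hardy-Weinberg
  violation is planted via an inbreeding-style coefficient F that
  depletes heterozygotes (P(het) = 2p(1−p)(1−F)) — a single knob that
  moves the exact-test p.  Missing calls are injected independently.
  SNPs are generated independently: no linkage-disequilibrium structure.
- **Connectivity.** Generation runs *backward* from DC: per subject, node
  DC targets are drawn from per-group normals (defaults: associative
  cortex 0.017±0.004 HC vs 0.019±0.004 PD; motor 0.012±0.003 vs
  0.015±0.003; thalamus 0.007±0.002 vs 0.008±0.002; pallidum 0.006±0.001
  vs 0.005±0.001 — three nodes higher in PD, pallidum lower; the four
  remaining nodes group-equal at plausible magnitudes), truncated below
  at 5% of the group mean.  A symmetric non-negative edge matrix with
  zero diagonal matching those row sums is obtained by Sinkhorn-style
  scaling (relative tolerance 10⁻¹²), then each pair's fiber records
  (5-12 fibers, lognormal lengths around 60 mm, FA uniform on (0.3, 0.7))
  are rescaled in length so the pair's fiber-density weight equals the
  matrix entry exactly.  Rebuilding the connectome from the records
  therefore reproduces the drawn DC to numerical precision.  Raw
  tractography geometry is *not* modeled; only the DC distribution is
  faithful, which is all downstream stages consume.  ROI surface areas
  are plausible per-structure mm² values; they rescale edge weights and
  nothing else.
- **Clinical score.** MDS_UPDRS = 5 + 1100·DC_motor + 1700·DC_thalamus −
  3400·DC_pallidum + 5·rs9346876 + 4.5·rs363611 +
  4·(rs9346876×rs363611) − 900·(pallidum×rs6901583) + 1.2·GDS + 3·sex +
  0.15·age + Normal(0, 6).  Coefficients are scaled so each term
  contributes roughly 1.5-3.5 score points of standard deviation given
  the generator distributions, putting the realized R² near 0.7 and the
  score mean near 30 with sd ≈ 13 — a plausible mixed-cohort severity
  distribution.  Scores are clipped at 0 and the clip count is reported
  (clipping is ~0 at these defaults; silent clipping would bias
  parameter-recovery checks).  The realized design matrix is stored on
  the bundle so recovery tests refit the exact generating form.

**What passing tests show.** Calibration (type-I error, permutation
uniformity, CI coverage), exactness (HWE vs enumeration, DC round-trip,
ANOVA identities, LOOCV closed form), selection power, and the
qualitative model ordering (combined ≥ single-source) are established
*under the generator's assumptions*: Gaussian DC, independent SNPs, a
correctly specified linear truth, exchangeable noise.  Real diffusion MRI
and genotyping data violate all of these to some degree (LD, site batch
effects in the images, non-Gaussian DC, heteroscedastic scores), so the
suite validates the machinery, not the clinical effect sizes.

## Numerical choices

- HWE probabilities via the mode-outward recurrence (stable in float);
  the observed table's probability is compared with a 1 + 10⁻¹² relative
  tolerance so exact ties in the support are included, matching the
  rational-arithmetic enumeration to < 10⁻¹² for all n ≤ 30.
- Stepwise candidate removals are scored on column subsets of one
  prebuilt design matrix (least squares + F tail only); the committed
  model is refit fully.  This changes nothing numerically and makes
  100-seed selection studies cheap.
- Rank-deficient designs are refused with the offending columns named
  (greedy rank-growth identification); before stepwise, collinear terms
  are pre-pruned in order with a warning.
- Sequential SS via QR of the design in term order: SS per term is the
  squared projection of y on that term's orthonormal directions, which
  makes the decomposition identities exact to machine precision.
- Degenerate inputs: zero-variance nodes get p = 1 with a warning;
  constant SNPs are flagged untestable rather than raising mid-scan;
  empty fiber lists give edge weight 0; all-missing SNPs have undefined
  MAF and fail the missingness filter.
- Reproducibility: every stage derives an independent stream from the
  master seed via `SeedSequence([seed, crc32(stage)])`; association
  substreams hash (phenotype, SNP) labels, not positions.

## Pipeline conventions

- If no DC node survives Bonferroni, the two smallest-corrected-p nodes
  are carried forward; if no SNP reaches empirical p < α, the top-2 by
  empirical p are used for models B/C.  Both fallbacks are recorded and
  keep the pipeline runnable on unlucky seeds; with default effect sizes
  they engage rarely and select the planted features.
- Default problem sizes: 40+40 subjects, 12-SNP panel, 10,000
  permutations, interaction cap 30 (with an n > p + 2 guard so the
  80-subject design stays fittable).  Simulation studies in the test
  suite use 100-1,000 replicates with streamline synthesis skipped where
  only DC is needed — the DC table is drawn identically either way.
- PLINK-text output writes a `.snpinfo.tsv` sidecar (gene label, allele
  letters) alongside `.ped`/`.map` so genotype round-trips are exact;
  readers fall back to empirical minor-allele inference without it.

## Known limitations

- Hoehn & Yahr is collected by the generator's design scope but not
  offered as a model covariate; the MDS-UPDRS is treated as an opaque
  non-negative score.
- No relatedness (IBD) estimation, no reference-panel ancestry
  comparison, no imputation, no mixed-model kinship correction.
- The stepwise rule optimizes the overall model p, which at very strong
  signal can underflow to 0 and stop elimination early; this is a
  property of the rule itself and is left intact.
- LOOCV with a fixed term set inherits selection optimism; reported RMSE
  and r are conditional on the selected model.
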