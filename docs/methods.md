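# Methods

This note documents the statistical procedure the package implements, the
generative model behind the synthetic data, the defaults and why they were
chosen, and the numerical conventions for degenerate inputs.

## The analysis procedure

**Normalization.** Spectral counts are transformed as
`log2(count + pseudo_count)` with `pseudo_count = 5`; the pseudo count
exists to keep zero counts (undetected proteins) finite under the log.
The log counts are then quantile-normalized: every sample's value
multiset is replaced by the common reference distribution (the row-wise
mean of column-sorted values) while within-sample ranks are preserved.
Ties within a column receive the mean of the reference values their
sorted positions span — the standard convention. Two consequences worth
knowing: (i) with ties, the output columns' multisets are *not* exactly
identical, and the map is *not* exactly idempotent (tie averaging
perturbs a tied column's multiset; both properties are exact on tie-free
columns); (ii) a uniform multiplicative distortion of one sample is
rank-preserving and therefore completely removed by quantile
normalization — relevant to outlier modeling below. By default soluble
and pellet samples of the contrast are normalized jointly
(`qn_scope="all_samples"`); a per-fraction scope is available.

**Insolubility ratio.** Per subject, per protein: normalized pellet value
minus normalized soluble value (log2 units). Positive = pellet-
preferential. Subject-level pairing is derived from the sample manifest;
subjects lacking either fraction are dropped with a warning.

**Differential testing.** Two rankings:

* *Raw-fold ranking* (`method1_rank`): disease/control ratio of mean raw
  pellet counts, a Wilcoxon rank-sum test on the raw counts, and a Welch
  t test on the pseudo-counted quantile-normalized log values. When the
  control mean is exactly 0 the fold is computed on pseudo-counted means,
  `(mean_d + 5)/(mean_c + 5)`, so control-absent proteins get a finite
  fold; otherwise the fold is the plain ratio of raw means.
* *Fraction-normalized ranking* (`method2_rank`): per-protein difference
  of group-mean insolubility ratios (log2 fold change; linear fold is
  `2**log_fc`), Welch-tested across subjects. This is the ranking used
  for significance calling, since each subject serves as its own soluble
  control.

P values are adjusted by Benjamini–Hochberg (the only shipped method,
named in output headers). A protein is significant iff adjusted Welch
p < `alpha` (default 0.05) **and** |log2FC| > `lfc_threshold` (default
0.5), both strict.

**Outlier exclusion.** PCA (SVD, no scaling) is run on the per-protein
centered ratio matrix, subjects as observations. Each subject gets a
robust distance: the Euclidean norm over the first `n_pcs` (default 2)
components of robust z-scores, `(score − median) / (1.4826 × MAD)`. The
user-facing sensitivity parameter `k` (default 3) is a per-axis sigma
level, but a raw cut at `k` would flag some subject in most small-cohort
null datasets: the distance aggregates `n_pcs` squared z-scores (chi-,
not normal-, distributed), the MAD of ~16 subjects is a noisy scale
estimate, and the leading PCs are chosen to maximize variance, which
stretches extremes. The threshold is therefore calibrated by a matched
parametric bootstrap: Gaussian null matrices with the observed
per-protein robust scales and the bulk per-subject relative scales
(capped at the boxplot upper fence so a candidate outlier cannot inflate
the null it is judged against) are pushed through the same centering +
PCA + distance machinery (200 replicates, fixed internal seed), and the
threshold is the null max-distance quantile matching the per-subject
two-sided tail at `k` sigmas. Measured at defaults over 50 simulated
datasets: a planted outlier is recovered 100% of the time (and is the
only subject flagged), while some subject is falsely flagged in 2% of
null datasets. An analytic chi-quantile threshold (`calibration="chi"`)
is available for large cohorts. Flagged subjects are removed before any
differential testing; exclusion that would leave a group with fewer than
2 subjects is an error.

**Expression filter and Venn summary.** A protein counts as expressed in
a (group, fraction) cell when more than half of that cell's replicates
have a non-zero count — a strict majority, so exactly half at even n is
excluded. The Venn summary reports each cell's cardinality and the union.

**Over-representation.** One-tailed hypergeometric tail of the term
overlap in the hit set against a background that defaults to all proteins
observed in the experiment. `mode="ease"` (default) removes one hit from
the overlap before taking the tail — the conservative variant popularized
by DAVID. BH across tested terms; zero-overlap terms are skipped.

**Densitometry.** Band intensity / lane total gives a normalized level;
group means are expressed relative to the control-group mean of the same
fraction (control ≡ 1). Heatmap bins: |level − 1| ≤ 5% is "no change"
(white); percent decrease is binned (5,20], (20,40], (40,60], (60,80],
(80,100] as −1…−5 (light → darkest blue); percent increase mirrors this
as +1…+5 up to 2-fold, with (2,4]-fold as +6 and >4-fold saturating at +7
(dark red). The source description of the upper bins is internally tense
("each 20% change … up to a 2-fold change" vs "upper limits … at
4-fold"); this resolution honors all three printed anchors — level 0.2 is
dark blue, 0.9 light blue, and both 10-fold and 3000-fold saturate dark
red. Decrease bins are linear in percent decrease (matching "decreased by
80%"), not log-symmetric. Change classification (increased / decreased /
unchanged) is the sign of the bin. Anchor correlations are plain Pearson
r with two-tailed p across subjects; pairs with <3 complete observations
or zero variance are reported missing with a note.

**Gel migration.** A protein is an anomalous migrator when it is observed
(disease + control counts > 0) in a gel fraction whose lower apparent-MW
bound is ≥ 200 kDa while its predicted mass is ≤ 51 kDa (boundary
inclusive). Disease/control folds are pseudo-count-guarded,
`(d + 5)/(c + 5)`; the headline count is the number of flagged proteins
with fold strictly over 50.

## The synthetic-data generator

`simulate_pelletome` draws, per protein, a total abundance (log-normal
across proteins) and a baseline pellet share p ∈ (0.25, 0.75); per
subject, a depth factor; the expected total count `abundance × depth` is
split between pellet and soluble by the share, and counts are negative
binomial per fraction. Disease acts on the *partition*, not total
abundance: for shifted proteins the pellet share's base-2 logit moves by
`effect_log2`, which shifts the expected pellet/soluble log2 ratio by
exactly `effect_log2` (depth cancels in the ratio). The truth table marks
shifted proteins and their signed shift.

Defaults and rationale:

* `n_per_group = 8`, `n_proteins = 3000` — the motivating cohort design
  (8 vs 8 subjects, ~3000 proteins identified across fractions).
* `frac_shifted = 0.1`, `effect_log2 = 1.0` — roughly one protein in ten
  with a 2-fold partition shift, matching the scale of the motivating
  study's significant set (~11% of the proteome).
* `baseline_abundance = (4.5, 0.8)` (ln-scale) — median ≈ 90 total
  spectral counts per protein, 95% range ≈ 18–450: the regime of
  proteins that pass an expressed-in-majority filter. The recovery
  properties (a 2-fold shift detectable at n = 8/group) are properties of
  this calibration.
* `dispersion = 20` (NB size) — between-subject CV ≈ 22% on top of
  counting noise, plausible for age-matched human cohorts.
* `depth_range = (0.8, 1.25)` — ±25% run-to-run depth variation,
  representative of nominal equal-load label-free operation; a 2-fold
  span would be an instrument QC failure, and since quantile
  normalization equalizes marginals but not noise levels, unrealistically
  wide depth spans turn low-depth subjects into genuine mild PC outliers.
* Outlier planting: one disease subject's pellet expectations are
  multiplied by `2**N(0, displacement²)` per protein (default sd 2.0 log2
  units). A *uniform* column factor would be erased by quantile
  normalization (rank-preserving), so the planted mechanism is
  compositional scrambling — the minimal distortion that survives
  normalization and that a PC plot reveals. The outlier channel draws
  from its own seeded stream, so planting perturbs no other draw.

What the generator does **not** emulate: peptide-level identification and
shared-peptide inference, protein–protein abundance correlation,
missing-not-at-random dropout of low-abundance proteins, batch structure,
and any coupling between total abundance and disease. Passing
plant-and-recover tests therefore demonstrates the pipeline's correctness
and calibration under this model, not performance guarantees on real
cohorts.

`simulate_gel_fractions` plants `n_aggregated` proteins with predicted
mass ≤ 51 kDa (one pinned exactly at 51 to exercise the boundary) in the
top gel fraction with folds drawn from `fold_range` (rounded so the drawn
fold is a lower bound); the remaining proteins sit in the fraction
matching their predicted mass with exchangeable counts.
`simulate_densitometry` plants per-(protein, group, fraction)
multiplicative levels with log-normal noise; at zero noise the relative
level recovers the planted effect exactly.

## Numerical conventions

* Welch's t: Welch–Satterthwaite df; both samples zero-variance gives
  p = 1 for equal means and p = 0 otherwise.
* Wilcoxon rank-sum: exact two-tailed p by enumeration (dynamic
  programming over rank sums, `2 × min(tails)` capped at 1) when the
  combined n ≤ 12 with no ties; otherwise the normal approximation with
  tie correction and 0.5 continuity correction. All-tied input gives
  p = 1.
* BH: step-up with monotonicity enforcement, capped at 1, input order
  preserved (delegated to statsmodels; verified against a hand step-up
  oracle).
* The 5%-band comparisons in the heatmap use a 1e-12 tolerance so that
  levels like 0.95 sit inside the band despite floating-point
  representation.
* Blank cells in count tables are read as 0: an undetected protein is an
  absence, not missing data.
* Problem sizes for the calibration experiments (20 datasets × 1000
  proteins for null calibration, 20 × 3000 for ranking recovery, 50 × 
  1000 for the outlier experiments) were chosen to make the Monte Carlo
  error on the reported rates small relative to the margins being
  checked.

## Known limitations

* The outlier rule assumes a single (or few) aberrant subjects; several
  simultaneous outliers would inflate the robust scales and partially
  mask each other.
* The EASE/Fisher test treats terms as flat sets — no ontology DAG
  propagation.
* Method-1's conditional pseudo-count guard makes the fold a
  discontinuous function of the control mean at 0; the Welch test driving
  significance is unaffected.
* Quantile normalization assumes comparable global distributions across
  samples; it cannot correct subject-specific noise inflation (see the
  depth discussion above), which is precisely what the PCA QC stage is
  for.
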