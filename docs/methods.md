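# Methods

## Ratio pooling model

Each protein p quantified in iTRAQ run i for a diagnosis contrast yields a
ratio rᵢ with a within-run variance vᵢ on the log2 scale. The model is a
standard two-level (random-effects) meta-analysis on yᵢ = log2 rᵢ:

    yᵢ = θ + uᵢ + eᵢ,   uᵢ ~ N(0, τ²),  eᵢ ~ N(0, vᵢ)

The pooled estimate is θ̂ = Σwᵢyᵢ/Σwᵢ with wᵢ = 1/(vᵢ + τ²); τ² is the
DerSimonian–Laird moment estimate truncated at zero (τ² ≡ 0 for the
fixed-effect variant), and the 95% CI is θ̂ ± 1.96·(Σwᵢ)^(−1/2), all
back-transformed to the ratio scale. A protein is called differential when
the ratio-scale CI excludes 1.

Choices worth stating:

- **Log scale.** Pooling happens on log2 ratios and is exponentiated back.
  "CI excludes 1" is only symmetric and well-behaved for a positive ratio
  after the log transform; the companion cross-fluid ANOVA likewise runs on
  log2 ratios.
- **DL estimator.** Non-iterative, the long-standing default of classical
  meta-analysis software; adequate for the ≤8 runs per protein seen here.
- **Normal CI, z = 1.96.** No small-sample t correction; this matches the
  classical random-effects summary CI. Known to undercover slightly when
  τ² must be estimated from few runs (measured ~96% with DL-estimated τ²
  at 8 runs in our calibration — the deviation is above, not below,
  nominal coverage because the truncation at zero widens intervals).
- **Singletons.** A protein observed in one run is "pooled" as that single
  observation with its own variance rather than rejected.
- **Variance provenance.** Per-observation variances are accepted as input
  (from upstream quantitation software) or estimated as the sample variance
  of replicate peptide-level log2 ratios divided by peptide count
  (`variance_from_peptides`); both paths are exercised in the tests.
- **Multiplicity.** The per-protein 5% CI rule is uncorrected by default —
  the analysis is an exploratory screen. `build_differential_table`
  exposes an optional Benjamini–Hochberg flag (off by default) that re-makes
  the calls on BH-adjusted z-test p-values within each comparison.

## Fixture tables and counting conventions

The packaged CSVs transcribe the published significant-protein tables:
110 saliva rows and 56 serum rows with three ratio columns, a per-cell
significance flag (bold in print — treated as data, not styling), run and
peptide counts, and a tumor-vs-normal AUC percentage. Conventions under
which the printed tallies reproduce exactly:

- The counting unit is the table **row** (accession); duplicate-protein
  rows (two A2MG, TSP1, SH3L1, ILEU entries) count separately.
- Up/down means ratio > 1 / < 1 among significant cells; no fixture ratio
  equals exactly 1.
- AUC tiers are half-open: ≥0.9 outstanding, [0.8, 0.9) excellent,
  [0.7, 0.8) acceptable; no fixture value sits on a boundary.
- The printed ">2 fold change" membership lists correspond to ratio-scale
  r > 2 among significant cells (direction up with fold ≥ 2), not to the
  symmetric fold max(r, 1/r) ≥ 2 in either direction.
- Known discrepancy: the serum M/B narrative count is 15 significant
  (4 up / 11 down), but the transcribed table carries 14 bold M/B cells
  (4 up / 10 down). Both numbers are recorded here; the serum M/B tally is
  deliberately excluded from the reproduction checks and from the
  acceptance report, and no guess is made about the missing cell.

## Cross-fluid comparison

Per protein, the additive linear model log2 ratio ~ fluid + diagnosis is
fitted by least squares (unbalanced cells handled naturally) and the fluid
factor is tested with Type-II (marginal) sums of squares; with two levels
per factor and no interaction, Type II and III coincide for balanced data.
A factor observed at a single level makes the test inestimable and is
reported as such rather than as a number. Within-fluid contrasts use the
classical pooled-variance two-sample t-test (Welch variant exposed).
Screening flags proteins at unadjusted p < 0.05, mirroring the exploratory
convention; per-protein models are fitted rather than one joint model.

## Over-representation analysis

One-sided Fisher exact test per gene set: p = P(X ≥ k) for hypergeometric
X with universe size N, set size K (after intersecting the set with the
universe) and query size n; BH correction across the collection; q < 0.05
flagged. The default universe is the detected-protein list of the
experiment at hand, not the genome — a genome universe inflates enrichment
because biofluid proteomics detects a biased, secretion-heavy fraction.
Depletion testing is out of scope.

## PPI subnetworks

"Seeds plus first neighbors" is interpreted as the **induced subgraph**:
node set = seeds ∪ {v adjacent to a seed}, edge set = all interactome edges
within that node set, so neighbor–neighbor edges are retained. This is the
reading under which published first-neighbor edge counts generally exceed
the pure seed–neighbor star count. Symbols are matched case-insensitively
with no automatic synonym resolution (silent alias mis-mapping is worse
than a missed match); seeds absent from the interactome are kept as
isolated nodes so the output always accounts for every query protein. Only
rows typed "physical" are read from BioGRID tab3 files. Hub ranking is by
degree within the subnetwork, ties broken lexicographically.

## Survival stratification

`fit_cox` maximizes the Cox partial likelihood over the marker genes
(delegated to lifelines; simulated event times are continuous, so tied
event times — where tie-handling conventions would matter — are absent).
Degenerate designs (constant covariates, collinearity, monotone likelihood
from separation) are flagged non-converged instead of returning silent
garbage. The prognostic index PI = Σβᵢxᵢ is the fitted linear predictor;
subjects are split at the **median PI** (≥ median → high risk), the
convention that keeps groups balanced; the threshold rule is a config
option. Groups are compared by the log-rank test and by the hazard ratio
exp(β) of a univariate Cox fit on the dichotomized group indicator (not
the continuous PI), with a 95% Wald CI. β is fitted in-sample on the same
cohort that is stratified, matching the usual prognostic-signature
pipeline; nothing here corrects for the optimism of in-sample evaluation.

## ROC evaluation

AUC is computed by the midrank (Mann–Whitney) statistic, giving tied pairs
half credit — exactly P(s⁺ > s⁻) + ½P(s⁺ = s⁻). The curve is a threshold
sweep over unique scores. Tier boundaries are the half-open intervals
stated above. Confidence intervals on AUC are out of scope.

## Synthetic data: what it emulates and what it does not

- **iTRAQ ratios** follow the same two-level log-normal model the pooling
  assumes, with planted log2 folds on a chosen fraction of proteins and a
  random per-protein subset of detected runs. Defaults mirror the study
  scale: 8-plex runs, within-run log2 SD 0.3, between-run SD (τ) 0.1,
  10% differential proteins at 1 log2 unit. Not emulated: peptide- and
  spectrum-level structure, reporter-ion ratio compression, missingness
  correlated with abundance, or batch effects beyond run-level
  heterogeneity. Passing tests therefore certify the statistics under the
  stated model, not robustness to those real-data artifacts.
- **Survival cohorts** are exponential proportional-hazards with N(0,1)
  expression and independent exponential censoring whose rate is matched to
  the requested censored fraction at the average hazard — the simplest
  mechanism satisfying the Cox model's assumptions.
- **Tumor/normal expression** shifts marker genes by δ in the tumor class
  under unit variance, so a marker's theoretical AUC is Φ(δ/√2); δ = 1.19
  gives AUC ≈ 0.80 and is used as the closed-form anchor.
- **Interactomes** are uniform random simple graphs with an exact edge
  count — no degree heterogeneity or community structure; network stages
  are checked for correctness, not for topology realism.

All generators are deterministic given their seed.

## Problem sizes and numerical choices

Calibration studies use: 2000 null proteins for CI coverage (pooled with
the known simulation τ², the condition under which nominal 95% coverage is
exact); a 1000-protein planted simulation at 8 detected runs for
power/false-call rates; 2000 null replicates each for the ANOVA and
log-rank type-I checks (Monte-Carlo SD ≈ 0.5 percentage points); n = 2000
cohorts for Cox β and hazard-ratio recovery; n = 20 000 samples for the
closed-form AUC anchor. Convergence and tolerances: lifelines' default
Newton convergence for Cox fits; DL τ² truncation at 0; variance floor of
1e-12 on the log2 scale in the generator so noise-free configurations stay
valid inputs; CSV/TSV interchange writes 17 significant digits and reads
with round-trip float parsing so artifacts are bit-reproducible.

## Known limitations

- External-data results (the TCGA-derived per-protein AUCs and KM/HR
  figures, BioGRID-version-dependent network counts) are reproduced
  *structurally* on synthetic stand-ins — same statistic types, not the
  same numbers.
- The per-run variance model treats upstream-supplied variances as known;
  uncertainty in the variances themselves is not propagated.
- ORA assumes gene sets and query use the same symbol namespace; no
  identifier mapping is performed.
- The cross-fluid ANOVA treats per-run ratios as independent observations;
  within-subject pairing between fluids is not modeled.
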