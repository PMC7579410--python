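# Methods

This note documents the models, defaults and numerical choices behind
`plasmalfq`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The analysis model

Each protein's log2 LFQ abundance is tested with a one-way ANOVA using
sampling day as a fixed factor and the individuals within a day as
replicates. For the default design (k = 10 days, r = 6 fish) the F statistic
has df (9, 50), and R² = SS_between/SS_total measures the fraction of a
protein's variance explained by sampling day. Benjamini–Hochberg step-up
adjustment is applied once across the retained panel (m = number of retained
proteins); per-family or per-cluster correction is deliberately not offered.

Because the design is balanced (every fish sampled every day), any additive
per-fish intercept cancels exactly in the between-day sum of squares while
inflating the within-day sum of squares. Two consequences are worth
spelling out:

* **The R² boundary.** With R rejections among m tests at FDR level q, the
  BH raw-p boundary is Rq/m; inverting the F(k−1, k(r−1)) tail there and
  mapping F to R² gives R²\* = (k−1)F\*/((k−1)F\* + k(r−1)). At m = 278,
  R = 41, q = 0.05, df (9, 50) this evaluates to 0.3445 — the boundary
  reported as "R² > 0.34" in the CLI. Because R² is a monotone function of
  the raw p at fixed balanced df, the BH-selected set is *exactly* the set
  with R² above this boundary; the test suite asserts this self-consistency
  on every panel run.
* **Repeated measures.** Treating the six fish as independent replicates
  within each day ignores the repeated-measures structure. With a nonzero
  shared fish intercept the F test is conservative (fish effects inflate
  only the denominator), so raw p-values are stochastically above uniform.
  The package reproduces this classical design choice rather than replacing
  it with a mixed model; p-value calibration is therefore verified on the
  exchangeable null (no fish intercepts), which is the F test's own
  reference distribution. On cohorts with individual variance the procedure
  errs toward fewer rejections, never more.

Post-hoc day contrasts use the studentized-range (Tukey; Tukey–Kramer SE
for unbalanced groups) with compact letters built by insert-and-absorb:
start from one letter covering all days, split it at each significant pair,
drop columns nested in others; two days share a letter iff their contrast is
not significant. Letters are computed only for BH-significant proteins.

Assumption checks are reported, never used to exclude proteins: normality
of residuals by Anderson–Darling with estimated mean/variance (statistic as
in scipy; the p-value from the standard small-sample-corrected approximation
A²\* = A²(1 + 0.75/n + 2.25/n²) with the piecewise exponential formula,
which scipy does not expose directly), and variance homogeneity by the
median-centred (Brown–Forsythe) Levene variant.

PCA is SVD on the centred (optionally unit-variance-scaled) sample × protein
matrix, matching the semantics of R's `prcomp`: scores are the projections
onto right singular vectors, variance proportions are normalised squared
singular values.

## Protein grouping and duplicates

Tryptic digestion cleaves C-terminal to K or R except before P; peptides
spanning up to 2 missed cleavage sites are kept, filtered to 7–35 residues
(configurable). Group assembly is greedy: proteins ranked by (descending
peptide count, ascending accession); the top unassigned protein leads a new
group and any unassigned protein joins when ≥ 50% *of its own* peptides are
shared with the lead. The asymmetric denominator guarantees subset
absorption (a protein whose peptides nest inside another's always co-groups)
— the behaviour group-based quantification tools show for indistinguishable
isoforms. Membership is tested against the lead only, not transitively
against later joiners; this keeps the pass deterministic and single-sweep
and is a documented limitation. The deterministic ranking makes output
independent of input order.

Pairwise identity uses a global aligner (match +1, mismatch −1, gap open
−10, gap extend −0.5 — heavy gap penalties suited to closely related
paralogs; configurable), with alignment columns trimmed to the shorter
protein's aligned span so terminal overhangs don't dilute identity. The
shared-peptide denominator is the smaller peptide set, so nested sets score
100% — consistent with duplicate pairs reaching 100% sharing without being
identical. A Jaccard alternative exists behind the summary utilities for
sensitivity analysis. Duplicate detection (>70% identity and mutual length
coverage) uses the built-in aligner rather than an external BLAST
dependency; at these coarse cutoffs the two agree. Whole-genome-duplication
(homeolog) labels come from generator metadata or a user-supplied
homeologous-chromosome pairing table; no genome lookup is performed.

## Preprocessing

The presence filter retains a protein only when observed on ≥ 7 of the 10
sampling days for *every* individual. Zero or blank intensities in input
tables are treated as non-detections (missing), matching the convention of
label-free search-engine output where a zero intensity means the feature was
not found. Imputation runs on the log2 scale:

* **random_forest** (default): missForest-style iteration. Initialise
  missing entries at the per-(protein, day) observed mean; visit proteins in
  increasing-missingness order, regressing each protein's sample vector on
  all other proteins with a 100-tree forest (mtry = √(p−1) via
  `max_features="sqrt"`); stop when the relative change of the imputed
  values increases (returning the previous sweep) or after 10 sweeps.
  Deterministic given the seed.
* **knn**: sample-space k-nearest-neighbour imputation (k = 5), as a
  benchmark.
* **day_mean**: the initial fill alone — the natural "use the other fish
  that day" baseline.

Observed entries are never altered (asserted bitwise in the suite); an
imputed-flag matrix is carried on the tensor. Day-0 normalisation subtracts
each fish's day-0 value on the log2 scale — exactly the linear ratio
day d/day 0 — making day-0 entries 0 and removing between-fish baseline
differences. The IgM family aggregate is the arithmetic mean of log2 values
(a geometric mean on the linear scale), appropriate for closely related
proteins quantified multiplicatively.

## Profile clustering

Mean-over-fish profiles of the significant proteins (optionally plus the
mean-IgM and titre rows) are z-scored per row (display parity; Pearson
correlation is affine-invariant, so this cannot change the tree),
dissimilarity is d = 1 − r, and trees use complete linkage. The phrase
"correlation dissimilarity z-scores" admits several readings; z-score-then-
1−r is adopted and stated here. Seriation returns the leaf order consistent
with the dendrogram (branch flips) that minimises the sum of adjacent-leaf
dissimilarities — the natural formalisation of heatmap leaf reordering
against a fixed tree; the unconstrained multiple-fragment greedy path
(repeatedly join the globally closest fragment endpoints) is exposed as
`mf_path` for diagnostics. Flat clusters default to k = 5 with the k = 2
major split also of interest; cluster ids are renumbered contiguously along
the seriation order.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

    y[p,f,d] = baseline_p + s_p · fish_f + e · a_p(d) · 1{p responder} + ε

| parameter | default | meaning |
|---|---|---|
| n_individuals | 6 | fish sampled repeatedly |
| days | 0,7,14,21,28,35,42,56,70,84 | days post-immunization |
| n_proteins | 278 | retained panel size |
| responder_fraction | 0.15 | fraction with day effects (→ 42 responders) |
| sigma_individual | 1.0 log2 units | SD of the per-fish intercept `fish_f` |
| sigma_noise | 0.35 log2 units | residual SD ε |
| effect_size | 0.70 log2 units | peak day-effect amplitude (= 2·sigma_noise) |
| responder_individual_scale | 0.25 | attenuation `s_p` of the fish intercept for responders |
| baseline_mean / sd | 25 / 1 | log2 intensity baselines |
| missing_rate | 0.0078 | target post-filter missingness |
| mnar_strength | 1.0 | logistic slope of missingness on abundance z-score |

The per-fish intercept is shared across proteins, producing the
individual-dominated global structure plasma proteomes show (samples group
by fish in PCA). The intercept is *attenuated* for responder proteins: in a
balanced one-way analysis any fish intercept enters the error term, so
population-level markers are detectable precisely to the extent that their
within-day abundances agree across individuals — the defining property of a
population response. An unattenuated intercept of realistic size would make
day effects of 2×noise undetectable by construction; s_p = 0.25 encodes
"responders respond consistently" without eliminating individual variation.

The five archetype profiles are fixed centred templates spanning [−1, 1]
over the ten days — late single peak (A1), slow monotone rise (A2), day-7
spike then elevated plateau (B1), mid-course peak with a day-56 trough (B2),
and early-high decaying (B3) — chosen so each shape is qualitatively
distinct under Pearson correlation and carries enough day-to-day variance
for the recovery contracts. `effect_size` multiplies the template, so it is
the peak amplitude in log2 units.

Missingness is modelled MNAR: entries are masked with probability
logistic(α − mnar_strength · z), where z is the global abundance z-score and
α is calibrated by bisection so the expected masked fraction equals
`missing_rate`; mnar_strength = 0 recovers MCAR. Titres follow a logistic
rise with per-fish onset uniform in 21–42 days and per-fish amplitude; at
coupling = 1 the same latent curves (plus noise) are added to designated IgM
proteins, so titre and mean-IgM abundance correlate by construction.

All randomness is split from one seed by hashing (stream, key) tuples into
`SeedSequence` spawn keys, so enlarging a design never perturbs draws for
existing proteins, fish or peptides.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: peptide-level intensities and their roll-up
into LFQ values; between-run normalisation artefacts; correlated protein
modules beyond the single shared fish intercept (real plasma proteins
co-vary in pathway blocks, which makes forest imputation look *better* here
than the hardest real cases); protein-specific missingness mechanisms; and
drift or batch structure over the timecourse. Recovery and FDR figures are
statements about this generative model at these defaults, not about any
particular instrument or cohort.

## Numerical choices and degenerate inputs

* p-value calibration checks use the exchangeable null (sigma_individual =
  0, effect_size = 0); see "Repeated measures" above for why.
* The empirical between-fish variance check averages over many seeded
  cohorts: a single 6-fish cohort estimates a variance with 5 df (±63%
  sampling CV), so no single-cohort assertion is meaningful.
* ANOVA on identical values, constant clustering rows, empty peptide-set
  denominators, zero rank variance, missing day-0 columns and non-positive
  intensities before log2 all raise errors naming the offending feature.
* Ties in group seeding break by accession; ties in linkage follow the
  deterministic scipy ordering; equal-identity substitution targets round to
  the nearest achievable count rather than failing.
* Problem sizes in the test and acceptance runs (20 null cohorts, 3-seed
  recovery/imputation/clustering replicates, 100-instance grouping oracle,
  50 paralog pairs) were chosen as the smallest replications that make the
  pass/fail contracts statistically stable.

## Known limitations

* Group membership is lead-anchored, not union-anchored; whether real
  grouping engines evaluate sharing against the lead or the group union is
  not documented, so the threshold and semantics are configurable.
* The one-way ANOVA ignores the repeated-measures correlation (by design,
  for fidelity); a mixed-model alternative is out of scope.
* "% similarity" is reported strictly as percent *identity*; substitution-
  class similarity is not computed.
* The seriation objective fixes one reading of heatmap leaf ordering
  (minimal adjacent dissimilarity under branch flips); other tools may use
  different flip objectives and produce different, equally valid orders.
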