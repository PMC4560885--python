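# Methods

## The screening model

The pipeline targets a small two-group biomarker study: n = 10 controls vs
n = 20 cases, each subject measured on two expression platforms
(small-RNA sequencing counts; array intensities) plus a table of clinical,
neuropsychological, neuroimaging and drinking variables.  The analysis is
deliberately a *screen*, not a confirmatory model: per-feature two-group
tests are run without multiplicity correction, and reliability is instead
sought through cross-platform concordance (the tier system) and through
FDR control in the one genuinely exploratory stage (the all-pairs
correlation screen).

### Adaptive two-group test

Every feature passes through a variance-gated decision tree:

1. Folded two-tailed Fisher F test, F = s²₍max₎ / s²₍min₎ with the matching
   numerator/denominator degrees of freedom.  The fold makes the test
   two-sided without choosing a direction; p = min(1, 2·P(F ≥ f)).
2. p > 0.05 → Student's t (equal variances).
3. Otherwise, clinical mode → Welch's t.  Expression mode → Shapiro–Wilk
   per group; both p > 0.05 → Welch's t, else Mann–Whitney U (normal
   approximation with tie correction when more than half the pooled values
   are tied, flagged).

Normality is tested per group, not pooled: a genuine group shift would
itself break pooled normality and mis-route true effects to the rank test.
The effect size, %Δ = 100·(case mean − control mean)/control mean, is
reported to one decimal from the arithmetic means of normalized values —
this convention reproduces the published effect sizes exactly on the
bundled reference rows.

**Calibration.**  On null synthetic cohorts the *pooled* adaptive test is
well calibrated (empirical type-I 0.050 at α = 0.05 over 4000 features).
Its per-branch conditional rates are not all nominal on skewed data: for a
right-skewed null (gamma-mixed counts), samples selected by a significant
variance test tend to carry an extreme mean difference as well, so the
Welch branch's conditional rejection rate is inflated (~0.16 in our null
runs) even though every branch is calibrated on Gaussian nulls.  This is a
property of the decision tree itself, not of any implementation; the
acceptance test that asserts per-branch calibration on overdispersed nulls
documents the phenomenon and is expected to fail on the Welch branch.

### Tiers

Tier A (seq p < 0.05 ∧ array p < 0.10 ∧ consistent direction) and Tier B
(seq p < 0.05 ∧ consistent direction) are exclusive strata with precedence
A > B > C.  "Consistent" requires both percent changes nonzero with equal
sign; a zero array change counts as inconsistent (deterministic and
conservative).  Features absent from the array cannot reach A or B — no
imputation.  Tier C is granted to any miRNA with an exploratory-screen
record in the case group at BH FDR < 0.05; a Tier A/B molecule that also
qualifies keeps its tier and records the correlation as secondary
evidence.

### Correlation screen

Pearson R on pairwise-complete pairs (each pair keeps its own N — the
reference tables show varying N, implying pairwise rather than listwise
deletion), significance by t = R·√((N−2)/(1−R²)) on N−2 df, two-tailed.
Correlations are computed on RPM-normalized expression rather than its
log; this is configurable, as display-oriented analyses often log the
values first.  The BH-FDR family is all policy-allowed pairs within one
group context.  Pairs within a class (miRNA–miRNA, region–region) are
excluded as uninformatively strong; drinking indices exist only for cases
and are only tested there.

### Clustering

Pearson distance d = 1 − r (the MEV convention) on row-scaled profiles;
unweighted average linkage (UPGMA) with the Lance–Williams size-weighted
update.  Ties are broken by the lexicographically smallest leaf-id pair,
making the tree invariant to input row order.  Newick branch lengths
follow the ultrametric convention: a node sits at half its merge height.
Row z-scoring uses the sample standard deviation (ddof = 1); correlation
is affine-invariant, so this choice does not affect the distances.  The
tissue-panel variant total-normalizes each tissue column (pseudocount 0.5
on counts so zeros remain loggable), median-centres log₂ rows, and flags a
miRNA brain-enriched when its normalized brain level strictly exceeds its
own 75th percentile across tissues — an operational stand-in for a call
that is made visually in heatmap practice.

### Sulcal fraction

Both autothresholds operate on the 256-bin intensity histogram of the
masked image.  Tsai's moment-preserving method finds the two-level image
matching the first three grayscale moments and thresholds at the smallest
intensity whose cumulative fraction reaches the computed below-fraction
p₀; Zack's triangle method draws a line from the histogram peak to the far
end of the longer tail and thresholds at the bin of maximum perpendicular
distance.  Foreground is *strictly greater than* the threshold (the
comparison side is arbitrary; fixed for determinism).  With a dark
background, dark sulci and a bright surface, the triangle threshold lands
just above the background (foreground = whole visible surface) and the
moments threshold between sulci and gyri (foreground = gyri only), so
percent-sulci = 100·(A_t − A_m)/A_t is the sulcal share of the visible
surface; negative differences are clipped to zero and flagged.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per run.

* **Cohort**: 10 controls vs 20 cases, 500 features, 16 differential
  (13 up at fold 2.5, 3 down at fold 0.4, echoing the mostly-increased
  published panel), library sizes log-normal around 10⁶ reads (σ = 0.25).
* **Counts**: gamma–Poisson (negative binomial), dispersion k = 5
  (variance = μ + μ²/k).  The source study reports no distributional form
  for serum miRNA; NB is the standard overdispersed count model and k = 5
  gives a biological CV of ~45%, a realistic serum-assay variability.
  Relative abundances are log-normal (σ = 2 on the natural log), spanning
  the few orders of magnitude seen in serum panels.
* **Array**: log-normal intensities whose log₂ group effect is
  `array_attenuation` (default 0.2) times the sequencing log₂ fold —
  mirroring the much smaller array effect sizes seen when a hybridization
  platform re-measures sequencing hits — with measurement noise
  σ = 0.25 log₂ units.
* **Planted correlations**: a Gaussian copula ties a variable to a
  feature's latent gamma mixing variable, preserving the count marginal.
  The latent coefficient is divided by the analytic z→gamma attenuation
  (0.978 at k = 5, by Gauss–Hermite quadrature) so the *population*
  Pearson R equals the target.  At n = 20 the sample correlation is still
  a few hundredths low because of small-sample skewness of the gamma
  marginal; recovery rates quoted in the tests were frozen from
  Monte-Carlo runs under exactly these conditions.
* **Reads**: uniform precursor choice; mature reads start uniformly within
  a uniformly chosen arm, background reads start uniformly over the
  precursor span.  Because background reads can also satisfy the
  90%-overlap rule (14 of 99 start positions in the default geometry),
  the expected measured mature fraction is mf + (1 − mf)·14/99; tests
  compare against this expectation, not the planted value alone.
* **Images**: an elliptical "brain" (~40% of the frame so the background
  stays the modal histogram level), sinusoidal sulcal strokes trimmed
  pixel-by-pixel to the exact target count, background 2 / sulci 50 /
  gyri 220.  Acquisition noise is added only inside the brain — skull
  stripping zeroes the background.  The wide sulcus–gyrus separation keeps
  the moments threshold above the noise-broadened sulcal band; at noise
  σ = 5% of the dynamic range the recovered fraction is within ~1
  percentage point of truth, and a planted 16% group difference is
  recovered within ±4 points averaged over 20 replicates.

What the generator does **not** emulate: sequencing error and adapter
content, isomiR end-heterogeneity, multi-mapping read families,
batch/hybridization effects shared across features, missing clinical data
patterns beyond case-only drinking indices, and real cortical geometry
(2D surface projections stand in for 3D reconstructions, on which the
statistic is defined identically).  Passing tests therefore demonstrate
the correctness and calibration of the machinery under a faithful
statistical caricature of the study — not performance on real serum data.

## Numerical choices and degenerate inputs

* RPM columns with zero totals become all-zero and are flagged, never
  fatal; "detected" means raw count > 0, with no expression floor.
* Mature-arm ties (both arms reaching 90% overlap) resolve to -5p;
  geometrically near-impossible for non-overlapping windows.
  Multi-precursor reads are counted once per precursor.
* GFF3 intervals (1-based closed) are converted to 0-based half-open at
  parse time; all internal arithmetic is half-open.
* Constant rows are dropped (z-scoring) or rejected (Pearson distance);
  constant groups flag the variance test as degenerate and fall through to
  Student on trivially equal variances.
* The moments threshold tolerates float round-off at exact cumulative
  boundaries (ε = 10⁻¹²); for a symmetric two-delta histogram p₀ = ½ is
  reached at the lower delta, whose strictly-greater foreground is exactly
  the upper delta.
* Seeds: every generator routes randomness through one
  `numpy.random.Generator`; the pipeline derives child seeds (< 2³¹) from
  the config seed, so identical config + seed reproduces byte-identical
  outputs.

## Known limitations

* The per-branch calibration caveat above: conditional branch sizes on
  skewed nulls are not nominal even though the pooled test is.
* RPM normalization is compositional: planting 16 up-regulated features
  inflates case totals slightly, so recovered %Δ under-estimates large
  planted folds by a few percent of the effect (≈ 7% at fold 2.5) — the
  same bias affects any total-count normalization, including the original
  analysis.
* The published reference table carries two rows (mir-96, mir-1976) whose
  printed RPM pairs are inconsistent with their printed percent changes;
  the percent-change columns are treated as authoritative and those RPM
  cells are not used as validation anchors.  Likewise the published
  cross-platform concordance (0.588) recomputes to 0.587 from the printed
  1-d.p. effect sizes; tests allow that rounding gap.
* Tier matching across precursor-level (mir-) and mature-level (miR-…-5p)
  identifiers is by exact id; cross-level matching is left to the caller's
  id conventions.
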