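# seromir

Serum extracellular miRNAs are promising minimally invasive biomarkers of
central-nervous-system damage in alcohol use disorder (AUD): fully processed
mature miRNAs circulate in blood, several are brain-enriched, and their
levels track clinical, neuropsychological and neuroimaging measures.
`seromir` implements, as a tested and reusable pipeline, the biomarker
discovery analysis of a small two-group serum miRNA study (20 AUD cases vs
10 age-matched controls, quantified on two platforms: small-RNA sequencing
and a hybridization array), together with a synthetic-data generator that
emulates the study's statistical structure so every stage can be validated
against known ground truth.

## What it computes

**Quantification.** Reads aligned to precursor (hairpin) coordinates are
assigned to a mature arm when ≥ 90% of the read overlaps the -5p or -3p
window on the same strand, RPM-normalized (counts / sample total × 10⁶),
and filtered to features detected in ≥ 5 subjects.  A maturity trend
profile bins read midpoints along relative precursor coordinates; serum
miRNA is almost fully processed, so the profile is bimodal at the mature
windows.

**Adaptive two-group test.** Each feature is first tested for equality of
variances with a folded two-tailed Fisher F test (F = s²₍max₎/s²₍min₎).
Equal variances → Student's t.  Unequal variances → Welch's t for clinical
variables; for miRNA expression, Shapiro–Wilk normality per group decides
between Welch's t (both normal) and Mann–Whitney U.  The effect size is
%Δ = 100·(x̄₍AUD₎ − x̄₍ctrl₎)/x̄₍ctrl₎.  P-values are nominal (uncorrected) —
the screen is for candidate discovery.

**Cross-platform tiers.**  With sequencing as the primary platform and the
array as validation:

* **Tier A** — seq p < 0.05, array p < 0.10, directionally consistent %Δ;
* **Tier B** — seq p < 0.05, directionally consistent %Δ, any array p;
* **Tier C** — miRNAs whose exploratory Pearson correlation with any
  clinical/neuroimaging variable in the case group survives
  Benjamini–Hochberg FDR < 0.05.

**Correlation screen.**  Pearson R on pairwise-complete observations;
significance via the R→T transformation t = R·√((N−2)/(1−R²)) with N−2 df.
The targeted screen (significant variables × Tier A/B miRNAs) is
uncorrected; the exploratory screen (all expressed miRNAs × all variables)
is BH-FDR-corrected over the whole family within a group context.
miRNA–miRNA and region–region pairs are excluded, and drinking indices are
correlated only within the case group.

**Clustering.**  Row z-scoring (or per-row median-centred log₂), Pearson
distance d = 1 − r, unweighted average linkage (UPGMA) with deterministic
lexicographic tie-breaks; Newick output.  A tissue-panel variant
total-normalizes columns and flags brain-enriched miRNAs.

**Sulcal morphometry.**  On a skull-stripped brain-surface image the
triangle (Zack) autothreshold includes the dark sulci in its foreground
while the moment-preserving (Tsai) threshold excludes them;
percent-sulci = 100·(A₍triangle₎ − A₍moments₎)/A₍triangle₎ measures the
fraction of visible surface occupied by cortical sulci, compared between
groups with the clinical decision tree.

## Worked example

```python
from seromir import study_config, generate_cohort, SerumBiomarkerModel

cohort = generate_cohort(study_config(seed=7))   # 10 vs 20, 500 miRNAs, 16 planted
results = SerumBiomarkerModel.from_cohort(cohort).fit()
print(results.summary())
```

```
Serum miRNA biomarker screen
============================================
Samples: 10 control vs 20 AUD
Features after detection filter: 500 (min subjects = 5)
Nominally significant (seq, p < 0.05): 44
Tier A: 15   Tier B: 15   Tier C: 0
--------------------------------------------
feature           tier    seq %ch   seq p  arr %ch   arr p
mir-sim-0071      A         180.4   0.000     26.7   0.000
mir-sim-0389      A         191.0   0.000     37.5   0.000
...
```

All 16 planted differential miRNAs are recovered in Tier A ∪ B for this
seed (the extra Tier B rows are the expected nominal false positives of an
uncorrected screen over 500 features — the reason the tier system demands
cross-platform concordance before a molecule is taken seriously).  The
same pipeline runs from the shell:

```sh
seromir run-all -c config.yaml -o results/
seromir quantify --reads reads.bed --annotation mirnas.gff3 -o counts.tsv
```

## Layout

| module | contents |
| --- | --- |
| `seromir.model` | `SerumBiomarkerModel` / `SerumBiomarkerResults` — the fitted screen |
| `seromir.simulate` | synthetic cohorts, reads, tissue panels, brain images + ground truth |
| `seromir.quantify` | read→feature counting, RPM / percent normalization, maturity trends |
| `seromir.groupstats` | F test, adaptive two-group test, %Δ, volume normalization |
| `seromir.tiers` | Tier A/B/C assignment and merging |
| `seromir.correlate` | Pearson screen, R→T, BH-FDR, pair policy |
| `seromir.cluster` | scaling, Pearson distance, UPGMA, tissue enrichment |
| `seromir.sulcal` | moments/triangle thresholds, percent-sulci, group comparison |
| `seromir.pipeline` / `seromir.cli` | YAML-driven end-to-end runs, `seromir` CLI |

See `docs/methods.md` for the statistical model, generator design and
known limitations.
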