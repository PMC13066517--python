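# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `aptaprofile`, in the order data flows through the pipeline.

## Edit distance and family joining

Two Damerau–Levenshtein variants are implemented over uint8-encoded
sequences:

* **Unrestricted** (default): the true metric allowing substitutions,
  insertions, deletions and adjacent transpositions, with transposed blocks
  re-editable.  Computed with the Lowrance–Wagner dynamic programme
  (alphabet-indexed last-occurrence table).  It is symmetric and satisfies
  the triangle inequality.
* **Restricted / OSA**: the common optimal-string-alignment variant in
  which no substring is edited twice.  It is provided behind a flag because
  popular libraries differ in which variant they call
  "Damerau–Levenshtein"; the two disagree on cases such as
  `CA → ABC` (2 unrestricted vs 3 restricted).  It is not a metric.

Family joining is a greedy, abundance-anchored single pass: sequences are
visited in descending total count (ties lexicographic); a sequence founds a
new family iff no existing representative lies within `d_max` (default 3),
otherwise its counts are added to the nearest representative, ties going to
the earlier-founded (higher-abundance) representative.  The rationale is
the data-generating process: high-abundance parents absorb their
low-abundance PCR/sequencing derivatives.  The pass is deterministic and
invariant to input row order, and conserves reads exactly.  A
single-linkage connected-components alternative is available
(`linkage="single"`) for small inputs.  The hot path is a numba-compiled
bounded DP with a length prefilter (`|len(a)−len(b)| > d_max` is an exact
exclusion) and row-minimum early abandon; row minima of the DP table are
non-decreasing, so abandoning once a full row exceeds the cutoff is exact
(this is additionally verified against exhaustive scans in the tests).

The min-count filter defaults to "≥ 3 reads in **every** sample"
(`presence_mode="all_samples"`), the reading that minimizes downstream
missing values; `any_sample` and `mean` modes are available.  Joining
precedes filtering.

## Normalization

Counts are compositional; only within-sample proportions carry signal.
Percent-of-total per sample followed by division by the per-sequence mean
percent yields scaled relative-binding values with per-sequence mean
exactly 1.  The scaling scope is **per cohort** (discovery means for the
discovery cohort, validation means for the validation cohort), since the
two cohorts are analyzed separately; the scope is configurable.  Scaled
values are invariant to per-sample depth rescaling (verified to 1e-9).
Under all-samples filtering, zero cells cannot survive to this stage, so
zero-mean sequences are a hard error.

## Discovery statistics

Each contrast is an unadjusted two-group OLS fit per sequence on the union
of the reference and study groups: `x ~ 1 + 1[study]`.  With a binary
predictor the indicator coefficient β equals the group-mean difference and
its t test (df = n−2) is algebraically the pooled-variance two-sample t
test; the implementation is vectorized closed-form OLS algebra and is
tested to machine precision against an independent t-test routine.
Repeated measures per participant are *not* modeled; contrasts are
marginal.  P values are BH-adjusted within each contrast (not pooled across
contrasts, since descriptive counts are reported per contrast), and the
descriptive call combines `p_adj ≤ q` (default q = 0.05) with an absolute
effect threshold `|β| ≥ δ` — δ = 1.0 for sampling-time contrasts, where
large compositional shifts between colostrum and mature milk are expected,
and δ = 0.2 for the subtler BMI-group and parity conditions.  Sequences
constant across all fitted samples get p = 1 with a warning; sequences
constant within each group but differing between groups (zero residual
variance, nonzero β) get p = 0 — never NaN.

The sampling-time panel is the union of the descriptive sequences of the
three later-vs-3-days contrasts; binary conditions have a single contrast.

## Panel validation

Panels are frozen after discovery; no re-selection happens on the
validation cohort.  The panel sequences' scaled values are mean-centered
per sequence — without unit-variance scaling, because scaled binding values
already share the mean-1 scale — and decomposed by SVD.  PC1 is oriented so
the study group's median score ≥ the reference group's, which makes
repeated runs bit-identical.  Panel sequences missing from the validation
matrix are dropped with a warning and reported as coverage.  Group
dispersion is the unbiased sample variance (ddof = 1).  Wilcoxon rank-sum
tests are exact when both groups have ≤ 25 observations and no ties,
otherwise normal approximation with tie and continuity corrections
(scipy's Mann–Whitney U).  Timepoint comparisons are each later timepoint
vs 3 days plus 1 month vs 3 months; binary conditions give their single
pair.

## Motif families

"Homology" among descriptive sequences is operationalized as k-mer
containment (default k = 7): for each k-mer in the panel, the number of
panel sequences containing it is tested against its empirical containment
frequency in the full retained library (one-sided binomial tail).  The
empirical background is used instead of an i.i.d. base model because
selection libraries are sequence-biased; k-mers absent from the background
get a half-count pseudo-frequency.  **The BH family is all 4^k k-mers**,
with the unobserved ones contributing p = 1: conditioning the family on
occurrence in the panel would hand every singleton k-mer a
guaranteed-small-ish p value (≈ n·p₀) and make them reject in bulk, ruining
null specificity.  With the full family, implanted motifs are detected at
p_adj ≈ 4^k·P(Binom(n, p₀) ≥ n) (astronomically small) while uniform
panels stay clean.  Enrichment additionally requires fold ≥ 2.

Enriched motifs are merged transitively when their member sets overlap by
≥ 50% of the smaller set or the motif strings share a (k−1)-mer.  A
family's representative is its member with maximal summed reads over both
cohorts (ties lexicographic); families are annotated with the conditions
whose panels contributed members, and panel sequences containing no
enriched motif are reported separately as singletons.  Candidate selection
ranks families per model group by representative read count and flags the
three selection criteria (high read count, conserved motif, model
representation).

## Pull-down profiles

`L[p,s] = log2(100·I[p,s]/Σ_p I[p,s])`, computed over **all** detected
proteins of a sample (so linear-scale abundances sum to 100); the top-25
display selection happens afterwards.  Detection is intensity > 0 by
default with a configurable minimum-intensity floor.  Classification:
background = detected in any negative control; model-unique(g) = detected
only in pull-downs of group g; shared = detected in ≥ 2 groups and no
negative.  Classification is invariant to per-sample rescaling.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not SELEX
chemistry: a library of `n_ancestors` distinct variable regions (36-mers
over A/C/G/U; DNA on FASTQ export, losslessly) with baseline proportions
`∝ exp(N(0, abundance_sigma))`; per-sample latent proportions
`w ∝ baseline × Π(applicable fold changes) × exp(N(0, biological_sigma))`
renormalized to 1 (compositional closure, matching the percent-of-total
view of sequencing); depth ~ Poisson(`depth_mean`); reads ~ Multinomial;
and per-read edit noise with probability `mutation_rate`, applying 1 to
`max_edits_per_read` uniform edits among substitution, insertion, deletion
and adjacent transposition — transpositions are included precisely so the
Damerau–Levenshtein metric (not plain Levenshtein) is exercised.  With
`well_separated`, ancestors are rejection-sampled to pairwise distance
> 2·d_max, which guarantees that every derived read joins its own ancestor
and no other.  A `balanced_groups` flag assigns exactly round(p·n)
participants to the study group for calibration designs.  Timepoint
effects are fold changes relative to the 3-day reference level.

Defaults and their reasoning:

| parameter | default | why |
| --- | --- | --- |
| `seq_length` | 36 nt | variable-region length of the profiled library |
| `n_participants` | 86 | discovery-cohort design (344 samples over 4 timepoints) |
| `depth_mean` | 10^5 | desk-scale stand-in for millions of reads per sample; all statistics are depth-invariant after normalization |
| `abundance_sigma` | 1.0 | log-normal baseline spread giving a realistic multi-order abundance range across the library |
| `biological_sigma` | 0.3 | per-cell log-normal noise, ~30% CV of relative binding |
| `mutation_rate` | 0.02 | per-read probability of 1–3 edits, producing the derivative clouds the joiner collapses |
| planted `fold_change` | 1.5–2 (binary), 3–4 (time) | condition effects are the artifact's own choice; per-sequence effect sizes are not published |

What the generator does **not** emulate: round-to-round SELEX enrichment
dynamics, sequence-composition bias of real libraries, PCR amplification
jackpots, position-dependent error profiles, or correlated
participant-level repeated measures.  Passing tests therefore demonstrate
the pipeline's correctness and calibration under its stated model, not the
biological validity of any real-data finding.

## Numerical and benchmark choices

* All randomness flows from a single integer seed per run; pipeline runs
  are bit-reproducible and record a manifest (config hash, seed, version,
  stage counts).
* Ties are always broken deterministically (descending total count, then
  lexicographic).
* Benchmark problem sizes: family recovery uses 1,000 well-separated
  ancestors × 20 samples at depth 10^5 with 2% edit noise; null
  calibration uses 200 cohorts of 500 sequences, 40 vs 40 samples at depth
  2×10^4 (depth chosen for turnaround; the statistics are depth-invariant
  after scaling, well above the filter floor); planted recovery uses 20
  replicates of 20/1,000 sequences at fold 1.5, depth 10^5, 40 vs 40, with
  an independently simulated validation cohort sharing the library seed.
* Planted-recovery sensitivity at those conditions runs ≈ 0.89–0.93 per
  20-replicate batch: the residual misses are planted ancestors whose low
  baseline abundance puts them under the ≥ 3-reads-per-sample filter or
  leaves too few counts for the BH-adjusted test — an intrinsic property
  of heavy-tailed library abundances, not a tunable defect.

## Known limitations

* The greedy joiner is order-optimal, not globally optimal; a derived
  sequence whose total count exceeded its ancestor's would found the
  family in its place (not observed under realistic error rates).
* No mixed-effects or longitudinal modeling; participant identity is used
  only for sample bookkeeping.
* Motif analysis is containment-based; alignment-level homologies longer
  than k with internal variation are only found via the (k−1)-overlap
  merge rule.
* Wilcoxon p values at validation are marginal per group pair; no
  cross-pair multiplicity correction is applied (matching the per-figure
  reporting style of the analysis this package implements).
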