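# Methods

## The procedure

Each Neurostatus-EDSS assessment is reduced to a 15-bit impairment profile
and clustered *within* its EDSS stratum, so that structure found by the
clustering is orthogonal to the ambulation-driven EDSS itself. The stages,
with the design reasoning behind each, follow.

### Subscore catalog

The 100 mandatory subscores are described by a catalog (`catalog.py`)
recording Functional System membership, laterality, legal grade range, the
"normal" grade, the binarization threshold and the side-merged feature each
item feeds. The public item list of the Neurostatus protocol is not
reproduced in the literature this package draws on; the Pyramidal,
Cerebellar and Sensory items feeding the 15 canonical features are modelled
faithfully (muscle-strength groups per limb and side on the BMRC 0–5 scale,
lateralized cerebellar and sensory items on 0–5 ordinal grades), while the
remaining Functional Systems are filled with plausibly named stand-in items
that only need to exist structurally. The catalog is a declared assumption,
serializable to YAML so an exact item list can be substituted.

### P/T adjustment and descriptives

Grades labelled `P` or `T` (deficits judged permanent/temporary and not
MS-related) are replaced by the item's normal value before any analysis;
the operation is idempotent and labels are kept for audit. Descriptive
summaries (EDSS histogram, per-EDSS five-number FSS summaries, cohort
counts) use plain order statistics.

Confirmed disability worsening (CDW) uses the standard baseline-dependent
thresholds: +1.0 over baseline for baselines 1.0–5.0, +0.5 for baselines
≥ 5.5, and — a convention, since the definition leaves it open — +1.5 for
baseline 0 (configurable). A worsening counts only if a visit at least
`confirmation_months` (default 6) later still meets the threshold; a
worsening at the final visit is therefore *unconfirmed*.

### Feature selection

Functional Systems are pre-selected either by whitelist (default:
Pyramidal, Cerebellar, Sensory — the published outcome) or, when the
whitelist is unset, as the top 3 by median (then mean) FSS over the
analysis range, with ties broken by canonical FS order. Subscores of the
retained FS are then side-combined to ordinal values (max impairment over
sides — the scale the filter operates on is not dictated by the source
procedure; pre-binarization ordinal grades retain the most information) and
filtered by the dual criterion:

* *uniformity*: modal-value share strictly above 0.85 excludes the feature;
* *correlation*: Pearson r strictly above 0.70 against an already-retained
  feature excludes the later one. Scanning follows canonical order, so
  which member of a correlated pair survives is deterministic.

Running uniformity first means zero-variance columns (undefined r) never
reach the correlation step. Correlations are pooled across the analysis
EDSS range rather than computed per stratum (the simplest reading;
switchable by filtering the input).

### Binarization

Thresholds live on the impairment scale: impairment > t ⇒ bit 1, with
t = 2 ("mild") for ordinal items, following the worked example in which all
grades up to *mild* map to zero. Muscle strength has a pre-step: per limb
region and side, impairment = 5 − min(BMRC grade), i.e. the worst muscle
dominates, with threshold t = 1 so that any muscle at BMRC ≤ 3 ("movement
against gravity" or worse) makes the region high — a reproduction of
"moderate or worse" semantics. Both the thresholds and the muscle rule are
configuration, since the exact published table is in unavailable
supplementary material. Lateralized features merge as the OR of per-side
bits (equivalently: 0 only if both sides are at or below threshold). The
map is monotone by construction: raising any grade can never clear a bit.

### Stratification and cross-validation

Strata are the half-point EDSS levels 4.0–6.5 (six data sets). Folds are
assessment-level (a plain three-way random split, sizes differing by at
most one), so one patient's visits may span folds; because the source
procedure does not address within-patient leakage, a patient-grouped mode
is provided (`by_patient=True`) for sensitivity analyses.

### Clustering engine

UMAP embeds the bit vectors into 2 (default) or 3 dimensions. The distance
metric is Jaccard by default: profiles are sparse bit vectors and shared
impairments should count for more than shared normality (Euclidean is a
parameter away). HDBSCAN (scikit-learn's implementation) clusters the
embedding and labels low-density rows −1 (noise).

Hyperparameter combinations are ranked by a **relative validity** score: a
simplified DBCV computed on the embedding, where each cluster's *density
sparseness* is the largest edge of its Euclidean minimum spanning tree, its
*separation* is the smallest distance to any other cluster, and per-cluster
validities (sep − sparseness)/max(sep, sparseness) are averaged with
cluster-size weights. Fewer than two clusters score −1 (worst possible;
full DBCV is undefined there), and tuning fails loudly if *no* grid point
produces two clusters. Ties break by grid order. An independent
implementation of the full DBCV definition (all-points core distances,
mutual-reachability MSTs restricted to internal nodes) is included as
`dbcv_check`, a small-scale oracle (n ≤ 2000) used to confirm that the
simplified score ranks candidate models the same way.

The reference grid is n_neighbors {15, 30, 50} × min_dist {0.0, 0.1} ×
n_components {2, 3} × min_cluster_size {1%, 2.5%, 5% of the stratum}. The
pipeline's routine grid (`small_grid`) is one embedding (n_neighbors 30,
min_dist 0, 2 components) × two cluster sizes, chosen to keep a six-stratum
run in the minutes range; both are plain parameter lists and any grid can
be passed explicitly. Embeddings are computed once per distinct embedding
parameter set and reused across cluster parameters.

*Model application.* Held-out rows are projected with the fitted UMAP
transform and take the majority label among their 5 nearest training
points in the embedding; a row whose nearest training point lies beyond
3 × the 99th-percentile nearest-neighbour distance of the training
embedding becomes noise. The source procedure says only that the trained
model is "applied" to validation data; nearest-neighbour membership around
the trained embedding is this package's concrete reading, and on planted
data it reproduces ≥ 90% of training labels when fed the training rows
back.

*Degenerate inputs.* Duplicate rows are clustered as-is (with 15 bits,
exact duplicates are the norm, not an accident). A table of *identical*
rows yields a defined embedding and either a single cluster or all-noise,
stable under a fixed seed; both outcomes are acceptable and tested. All
stochastic components (UMAP, fold shuffling, the generator) take explicit
seeds and runs are reproducible end to end.

### Pattern aggregation

A feature is *high* for a cluster when strictly more than 50% of the
cluster's assessments carry bit 1. Patterns apply with precedence
A > B > C > D — a profile with both motor and spasticity highs is A. The
precedence is an interpretation of the published group table (whose
rendering is ambiguous); it is explicit in `PatternRuleSet` and
configurable, as is the reading of pattern C ("any sensory/Romberg high"
by default; the literal "exactly one" reading via
`single_sensory_literal=True`). Enumerating all 2^15 high/low profiles
confirms the default rules form a total, four-valued partition. Noise rows
never enter profile denominators and are reported in a separate column of
every distribution table.

## The synthetic generator

The generator emulates the *structural* properties reported for the study
cohort: 1636 patients; visit counts drawn from N(8, 2.97²), rounded and
clipped at ≥ 1; EDSS drawn per assessment from stratum weights calibrated
so that ≈ 86% of assessments fall in 4.0–6.5 with the mode at 6.0 (the
published per-stratum counts divided by the published total, with the
remaining 14% spread over 0–3.5 and 7.0–8.5); age ≈ 48 ± 7.9; 60% female.

Latent structure is planted through four archetypes mirroring the pattern
groups (motor/cerebellar, spastic/tandem, sensory/Romberg, and
ambulation-only with no high features), mixed per stratum following the
published full-data pattern distribution — A's share rising with EDSS, D
vanishing by 6.5. For a designated-high feature the impairment grade is
drawn uniformly from 3–4 (clipped to exceed the threshold), otherwise
uniformly from 0–2 (clipped to at most the threshold); muscle-strength
impairment is realized by one randomly chosen carrier muscle per side.
Left and right grades agree with probability `side_correlation` (0.7).
Grade noise perturbs every grade ±1 with probability `grade_noise` (0.05),
clipped to legal ranges — at the default thresholds this flips roughly
1–2.5% of bits. P/T labels are injected at `pt_label_rate` (0.02).

`feature_dropout` (0.25 in the study-scale configuration, 0 in planted
test configurations) lets a designated-high feature be sampled low for an
individual assessment. Without it, archetype membership would make
within-group feature correlations ≈ 0.71 and the dual-criterion filter
would strip canonical features; with it, within-group correlations sit
near 0.4–0.5, comfortably inside the filter, while cluster profiles still
show ≈ 75% high shares — well above the 50% majority rule. Additional
candidate items are generated so selection has real work: rapid
alternating movements copy tremor grades and pain copies superficial
sensation (excluded by correlation), while reflexes, position sense of the
arms, figure writing and Lhermitte are drawn 90–95% at their normal value
(excluded by uniformity).

**What the generator does not emulate** — and therefore what passing tests
do *not* establish about clinical data: longitudinal within-patient
dynamics (EDSS and archetype are drawn independently per visit, so CDW
rates are emergent, not calibrated), treatment effects, age/sex effects on
subscores, and any subscore-level joint distribution beyond the archetype
co-occurrence assumption: real assessments may contain graded overlap
between impairment domains that no disjoint-archetype mixture reproduces.
Recovery results (ARI ≥ 0.8 at n = 900 per stratum and 5% grade noise)
certify the pipeline's machinery, not the discoverability of patterns in
any particular clinical cohort.

## Problem sizes

Routine runs and tests use scaled-down cohorts: 150–250 patients for
pipeline smoke runs, 600–900 assessments per stratum for recovery and
stability checks, 240 for validity-ranking comparisons — sizes at which the
planted structure is comfortably recoverable and a full six-stratum run
completes in minutes on one core. The study-scale configuration (1636
patients, ≈ 13,000 assessments) is the generator default and runs in
seconds for everything except clustering, which scales with stratum size
and grid size.

## Known limitations

* The catalog's item inventory outside Pyramidal/Cerebellar/Sensory is a
  structural stand-in; FSS values are derived as the maximum implied
  subscore severity, which is cruder than the official scoring algorithm.
* EDSS is assigned per stratum, never recomputed from FSS/AS; the package
  deliberately contains no Neurostatus scoring engine.
* The relative-validity score is computed on the embedding, so it compares
  *embedded* clusterings; it cannot rank embeddings against the original
  bit space.
* Approximate membership prediction can assign validation rows to noise
  near cluster boundaries; validation noise fractions are therefore
  slightly above training ones.
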