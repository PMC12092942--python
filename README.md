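# edss-patterns

Disability sub-patterns hidden inside identical EDSS scores.

The Expanded Disability Status Scale (EDSS) is the reference disability
measure in multiple sclerosis, but at scores ≥ 4.5 it is driven almost
entirely by ambulation: two patients with the same EDSS can have very
different deficits in strength, coordination or sensation. This package
implements, as a tested and reusable pipeline, a procedure for uncovering
those sub-patterns from standardized Neurostatus-EDSS assessments:

1. **Pre-processing** — grades flagged `P`/`T` (permanent/temporary deficits
   not attributable to MS) are replaced by their normal values.
2. **Feature selection** — the Functional Systems carrying the most
   disability (Pyramidal, Cerebellar, Sensory) are kept; their subscores
   pass a dual-criterion filter that drops any item with Pearson *r* > 0.70
   against a retained item or with > 85% of assessments sharing one value.
3. **Binarization** — each ordinal subscore (grades 0–5) becomes a bit:
   0 for *none / signs only / mild*, 1 for *moderate* and worse. Muscle
   strength first aggregates per side (worst muscle dominates, impairment
   = 5 − BMRC grade); lateralized items merge as the OR of per-side bits.
   The result is 15 canonical binary features per assessment.
4. **Stratification** — assessments are grouped by identical EDSS score
   (4.0–6.5 in half-point steps → six strata), optionally with three-fold
   cross-validation inside each stratum.
5. **Clustering** — each stratum is embedded with UMAP (Jaccard metric, 2–3
   components) and clustered with HDBSCAN; hyperparameters are chosen by a
   *relative validity* score, a simplified Density-Based Cluster Validity
   (DBCV) index. Trained models are applied to held-out folds via the
   fitted embedding map and approximate cluster membership.
6. **Patterns** — each cluster is profiled by the percentage of its
   assessments with bit 1 per feature ("high" if > 50%), then collapsed to
   one of four patterns with precedence A > B > C > D:
   * **A** motor/cerebellar (muscle strength, tremor/dysmetria, truncal or
     gait ataxia high),
   * **B** spasticity or tandem walking high,
   * **C** sensory/Romberg high,
   * **D** none high — disability reflects ambulation alone.

Because the underlying trial data are not public, the package ships a
first-class **synthetic cohort generator**: assessments draw an EDSS
stratum and a latent disability *archetype* (the planted ground truth,
stored in a reserved `truth_` column that the analysis never reads), and
subscore grades are sampled around the archetype with configurable noise,
left/right correlation and P/T labelling. The study-scale default
configuration reproduces the published cohort structure (1636 patients,
8 ± 2.97 visits, ≈ 86% of assessments in EDSS 4.0–6.5, mode at 6.0).

## Worked example

```python
from edss_patterns import RunConfig, run_full
from edss_patterns.synthetic_data import default_expandlike_config

config = RunConfig(
    generator=default_expandlike_config(n_patients=250, seed=3),
    out_dir="out",
)
report = run_full(config)
print(f"{report['descriptive']['n_assessments']} assessments, "
      f"{report['descriptive']['pct_edss_4_to_6_5']:.1f}% with EDSS 4.0-6.5")
for level, s in report["strata"].items():
    d = s["distribution"][0]
    shares = "  ".join(f"{p}={d[p]:5.1f}%" for p in "ABCD")
    print(f"EDSS {level}: n={s['n_assessments']:4d}  "
          f"clusters={s['n_clusters']:2d}  {shares}")
```

prints

```
2001 assessments, 83.4% with EDSS 4.0-6.5
EDSS 4.0: n= 164  clusters= 4  A= 29.9%  B= 28.0%  C= 16.5%  D= 25.6%
EDSS 4.5: n= 164  clusters= 3  A= 60.4%  B= 25.0%  C=  0.0%  D= 14.6%
EDSS 5.0: n= 145  clusters= 4  A= 46.2%  B= 20.0%  C= 15.9%  D= 17.9%
EDSS 5.5: n= 140  clusters= 4  A= 47.1%  B= 27.1%  C=  0.0%  D= 25.7%
EDSS 6.0: n= 561  clusters= 3  A= 72.9%  B= 21.9%  C=  0.0%  D=  5.2%
EDSS 6.5: n= 494  clusters=12  A= 95.0%  B=  5.0%  C=  0.0%  D=  0.0%
```

Each row is one EDSS stratum: the number of assessments, the clusters the
density clustering found, and the share of assessments falling in each
disability pattern. The share of pattern A grows with EDSS while D
vanishes — at EDSS 6.5 nearly all assessments also carry motor/cerebellar
impairment, whereas at 4.0 a quarter of them owe their score to ambulation
alone. `out/` additionally receives `report.json`, per-stratum cluster
profiles (`table4_profiles_<edss>.csv`), pattern distributions
(`table6_distribution.csv`) and row-level cluster labels.

The same pipeline is available from the shell:

```bash
edss-patterns simulate --n-patients 250 --seed 3 --out cohort.csv
edss-patterns describe --in cohort.csv --out summary.json
edss-patterns binarize --in cohort.csv --out features.csv
edss-patterns select   --in cohort.csv --out selection.json
edss-patterns cluster  --in features.csv --stratum 6.0 --seed 0 --out run/
edss-patterns run      --n-patients 250 --seed 3 --out out/   # full pipeline
```

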