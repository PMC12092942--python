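"""Cluster profiling and aggregation into the four disability patterns.

Within one EDSS stratum, each cluster is profiled by the percentage of its
assessments with high impairment (bit = 1) per feature; a feature is "high"
for the cluster when that percentage exceeds 50%.  Clusters collapse into
four patterns by feature group, with precedence:

* **A** — any motor/cerebellar feature high (muscle strength,
  tremor/dysmetria, truncal ataxia, gait ataxia);
* **B** — otherwise, spasticity or tandem walking high;
* **C** — otherwise, a sensory feature or the Romberg test high;
* **D** — none high (disability driven by ambulation alone).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarize import FEATURE_PREFIX, feature_columns

NOISE = -1

#: Feature groups behind patterns A-C (group D is "none of these high").
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "A": ("bmrc_upper", "bmrc_lower", "tremor_upper", "tremor_lower",
          "truncal_ataxia", "gait_ataxia"),
    "B": ("spasticity_upper", "spasticity_lower", "tandem_walking"),
    "C": ("romberg", "superficial_upper", "superficial_lower",
          "vibration_upper", "vibration_lower", "position_lower"),
}


@dataclass
class PatternRuleSet:
    majority_threshold: float = 50.0  # strictly above -> "high"
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_GROUPS.items()})
    precedence: tuple[str, ...] = ("A", "B", "C")
    fallback: str = "D"
    #: Literal reading of pattern C: exactly one sensory/Romberg feature high.
    single_sensory_literal: bool = False

    @property
    def all_features(self) -> list[str]:
        return [f for g in self.precedence for f in self.groups.get(g, ())]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.precedence + (self.fallback,)


@dataclass
class ClusterProfile:
    cluster_id: int
    n_assessments: int
    percent_high: dict[str, float]  # feature -> 0..100


def profile_clusters(feature_table: pd.DataFrame, labels: np.ndarray) -> list[ClusterProfile]:
    """Per-cluster percentage of assessments with bit 1, per feature.

    Noise-labelled rows are excluded; raises if no cluster remains.
    """
    labels = np.asarray(labels)
    if len(labels) != len(feature_table):
        raise ValueError("labels do not cover the feature table")
    cols = feature_columns(feature_table)
    ids = sorted(c for c in np.unique(labels) if c != NOISE)
    if not ids:
        raise ValueError("all rows are labelled noise; nothing to profile")
    bits = feature_table[cols].to_numpy()
    profiles = []
    for cid in ids:
        mask = labels == cid
        pct = 100.0 * bits[mask].mean(axis=0)
        profiles.append(ClusterProfile(
            cluster_id=int(cid),
            n_assessments=int(mask.sum()),
            percent_high={c.removeprefix(FEATURE_PREFIX): float(p)
                          for c, p in zip(cols, pct)},
        ))
    return profiles


def assign_pattern(profile: ClusterProfile, rules: PatternRuleSet | None = None) -> str:
    """Map one cluster profile to a pattern label (total and single-valued)."""
    rules = rules or PatternRuleSet()
    high = {f for f, p in profile.percent_high.items() if p > rules.majority_threshold}
    for label in rules.precedence:
        hits = high & set(rules.groups.get(label, ()))
        if label == "C" and rules.single_sensory_literal:
            if len(hits) == 1:
                return label
        elif hits:
            return label
    return rules.fallback


def pattern_distribution(feature_table: pd.DataFrame, labels: np.ndarray,
                         rules: PatternRuleSet | None = None,
                         by_stratum: bool = True) -> pd.DataFrame:
    """Percent of assessments per pattern (noise excluded, reported aside).

    Each assessment inherits its cluster's pattern.  Returns one row per
    EDSS stratum (or a single ``all`` row) with columns per pattern label,
    ``pct_noise`` and counts.
    """
    rules = rules or PatternRuleSet()
    labels = np.asarray(labels)
    cluster_pattern = {p.cluster_id: assign_pattern(p, rules)
                       for p in profile_clusters(feature_table, labels)}
    per_row = np.array([cluster_pattern.get(c, "noise") for c in labels])

    frame = feature_table[["edss"]].copy()
    frame["pattern"] = per_row
    frame["stratum"] = frame["edss"] if by_stratum else "all"

    rows = []
    for stratum, sub in frame.groupby("stratum"):
        counted = sub[sub["pattern"] != "noise"]
        row = {"stratum": stratum, "n": len(sub),
               "pct_noise": 100.0 * (len(sub) - len(counted)) / len(sub)}
        for lab in rules.labels:
            row[lab] = (100.0 * (counted["pattern"] == lab).mean()
                        if len(counted) else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def enumerate_rule_partition(rules: PatternRuleSet | None = None) -> set[str]:
    """Labels reachable over all 2^n high/low profiles (exhaustiveness check)."""
    rules = rules or PatternRuleSet()
    feats = rules.all_features
    seen: set[str] = set()
    for bits in itertools.product((0.0, 100.0), repeat=len(feats)):
        profile = ClusterProfile(0, 1, dict(zip(feats, bits)))
        seen.add(assign_pattern(profile, rules))
    return seen
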