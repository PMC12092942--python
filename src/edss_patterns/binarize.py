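"""Binarization of ordinal subscores into the 15 canonical binary features.

Each subscore grade is mapped to 0 ("none", "signs only", "mild" — low impact
on activities of daily living) or 1 ("moderate" and worse) by a per-subscore
threshold.  Muscle strength gets a pre-step: within each limb region and side
the *worst* muscle determines the side's impairment (BMRC 5 = full strength,
impairment = 5 − grade).  Lateralized subscores are merged: the feature is 0
only if both sides are at or below threshold, i.e. the OR of per-side bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import CANONICAL_FEATURES, SubscoreCatalog, default_catalog
from .ingest import subscore_column

FEATURE_PREFIX = "f_"
ID_COLUMNS = ["patient_id", "visit_index", "edss"]


@dataclass
class BinarizationSpec:
    """Thresholds and feature composition, defaulting to the catalog's.

    ``features`` is the ordered list of side-merged features to emit
    (default: the canonical 15).  Thresholds are read from the catalog and
    can be overridden per feature via ``threshold_overrides`` (impairment
    scale: impairment > t -> 1).
    """

    catalog: SubscoreCatalog = field(default_factory=default_catalog)
    features: list[str] = field(default_factory=lambda: list(CANONICAL_FEATURES))
    threshold_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        known = self.catalog.features()
        unknown = [f for f in self.features if f not in known]
        if unknown:
            raise KeyError(f"features not in catalog: {unknown}")

    def threshold(self, feature: str) -> int:
        if feature in self.threshold_overrides:
            return self.threshold_overrides[feature]
        return self.catalog.feature_threshold(feature)


def binarize_grade(subscore_id: str, grade: int, spec: BinarizationSpec) -> int:
    """0 iff the grade's impairment is at or below the subscore threshold."""
    sub = spec.catalog[subscore_id]  # KeyError for unknown subscores
    if not (sub.lo <= grade <= sub.hi):
        raise ValueError(f"grade {grade} outside legal range of {subscore_id}")
    t = spec.threshold_overrides.get(sub.feature, sub.threshold)
    return int(sub.impairment(grade) > t)


def aggregate_bmrc(side_grades: Sequence[int], spec: BinarizationSpec | None = None) -> int:
    """Per-side muscle-strength impairment: the worst muscle dominates.

    BMRC grades run 0 (no contraction) to 5 (normal); the side's impairment
    is ``5 - min(grades)``, fed to the threshold afterwards.
    """
    grades = list(side_grades)
    if not grades:
        raise ValueError("empty muscle-grade list for one side")
    if any(g < 0 or g > 5 for g in grades):
        raise ValueError(f"BMRC grades must lie in 0-5, got {grades}")
    return 5 - min(grades)


def merge_sides(left_grade: int, right_grade: int, subscore_id: str,
                spec: BinarizationSpec) -> int:
    """0 iff both sides binarize to 0; the OR of per-side bits."""
    return int(binarize_grade(subscore_id, left_grade, spec)
               or binarize_grade(subscore_id, right_grade, spec))


def _feature_bits(table: pd.DataFrame, feature: str, spec: BinarizationSpec) -> np.ndarray:
    subs = spec.catalog.features()[feature]
    t = spec.threshold(feature)
    by_side: dict[str, list] = {}
    for s in subs:
        by_side.setdefault(s.side, []).append(s)
    bits = np.zeros(len(table), dtype=bool)
    for side_subs in by_side.values():
        grades = table[[subscore_column(s.id) for s in side_subs]].to_numpy()
        if side_subs[0].kind == "bmrc":
            impairment = 5 - grades.min(axis=1)  # worst muscle per side
        else:
            impairment = grades.max(axis=1)
        bits |= impairment > t
    return bits.astype(np.int8)


def binarize_table(table: pd.DataFrame, spec: BinarizationSpec | None = None) -> pd.DataFrame:
    """One 15-bit feature vector per assessment.

    Returns a frame with ``patient_id, visit_index, edss`` identity columns
    followed by ``f_<feature>`` bit columns in spec order.
    """
    spec = spec or BinarizationSpec()
    out = table[ID_COLUMNS].copy().reset_index(drop=True)
    for f in spec.features:
        out[FEATURE_PREFIX + f] = _feature_bits(table.reset_index(drop=True), f, spec)
    return out


def feature_columns(frame_or_features: pd.DataFrame | Iterable[str]) -> list[str]:
    """The ``f_`` columns of a feature table (or prefix a feature list)."""
    if isinstance(frame_or_features, pd.DataFrame):
        return [c for c in frame_or_features.columns if c.startswith(FEATURE_PREFIX)]
    return [FEATURE_PREFIX + f for f in frame_or_features]
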