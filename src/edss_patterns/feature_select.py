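"""Feature selection: FS pre-selection and the dual-criterion subscore filter.

The descriptive analysis picks the Functional Systems carrying the most
disability (Pyramidal, Cerebellar, Sensory in the published cohort); their
subscores are then filtered by a dual criterion: a feature is dropped if it
is nearly constant (more than ``uniformity_max`` of assessments share one
value) or if it correlates with an already-retained feature above ``r_max``
(Pearson).  Values are side-combined ordinal grades (max over sides, on the
impairment scale), computed *before* binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CANONICAL_FEATURES, FS_NAMES, SubscoreCatalog
from .ingest import fss_column, subscore_column


@dataclass
class SelectionCriteria:
    #: FS retained outright; None means derive top-k from FSS medians.
    fs_whitelist: tuple[str, ...] | None = ("pyramidal", "cerebellar", "sensory")
    r_max: float = 0.70
    uniformity_max: float = 0.85
    top_k_fs: int = 3
    edss_range: tuple[float, float] = (4.0, 6.5)

    def __post_init__(self):
        if not (0 < self.r_max < 1):
            raise ValueError("r_max must lie in (0, 1)")
        if not (0 < self.uniformity_max < 1):
            raise ValueError("uniformity_max must lie in (0, 1)")


@dataclass
class SelectionReport:
    retained: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (feature, reason)

    def reasons(self) -> dict[str, str]:
        return dict(self.excluded)

    def to_dict(self) -> dict:
        return {"retained": self.retained,
                "excluded": [{"feature": f, "reason": r} for f, r in self.excluded]}


def preselect_fs(table: pd.DataFrame, criteria: SelectionCriteria) -> list[str]:
    """FS to carry forward: the whitelist, or the top-k by median (then mean) FSS."""
    if criteria.fs_whitelist is not None:
        return list(criteria.fs_whitelist)
    if len(table) == 0:
        raise ValueError("empty assessment table")
    lo, hi = criteria.edss_range
    sub = table[table["edss"].between(lo, hi)]
    if len(sub) == 0:
        sub = table
    stats = []
    for rank, fs in enumerate(FS_NAMES):
        col = sub[fss_column(fs)]
        stats.append((-col.median(), -col.mean(), rank, fs))
    stats.sort()
    return [fs for *_, fs in stats[: criteria.top_k_fs]]


def feature_values(table: pd.DataFrame, catalog: SubscoreCatalog,
                   features: list[str]) -> pd.DataFrame:
    """Side-combined ordinal value per feature: max impairment over subscores."""
    out = {}
    for f in features:
        subs = catalog.features()[f]
        grades = table[[subscore_column(s.id) for s in subs]].to_numpy()
        imp = np.stack([s.impairment(grades[:, i]) if s.kind == "bmrc" else grades[:, i]
                        for i, s in enumerate(subs)], axis=1)
        out[f] = imp.max(axis=1)
    return pd.DataFrame(out, index=table.index)


def _canonical_first(features: list[str]) -> list[str]:
    canon = [f for f in CANONICAL_FEATURES if f in features]
    return canon + [f for f in features if f not in canon]


def dual_criterion_filter(values: pd.DataFrame,
                          criteria: SelectionCriteria) -> SelectionReport:
    """Drop near-uniform features, then features correlated with a retained one.

    Scanning happens in canonical order (the canonical 15 first), so when two
    features exceed ``r_max`` the earlier, already-retained one wins.  Both
    cuts use strict inequality.  Near-constant features fall to the
    uniformity rule before any correlation is computed, so undefined Pearson
    r on zero-variance columns never arises.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 assessments to compute correlations")
    report = SelectionReport()
    order = _canonical_first(list(values.columns))

    survivors = []
    for f in order:
        frac = values[f].value_counts(normalize=True).iloc[0]
        if frac > criteria.uniformity_max:
            report.excluded.append((f, f"uniform:{frac:.2f}"))
        else:
            survivors.append(f)

    for f in survivors:
        hit = None
        x = values[f].to_numpy(dtype=float)
        for kept in report.retained:
            r = np.corrcoef(x, values[kept].to_numpy(dtype=float))[0, 1]
            if r > criteria.r_max:
                hit = (kept, r)
                break
        if hit is None:
            report.retained.append(f)
        else:
            report.excluded.append((f, f"correlated-with:{hit[0]}"))
    return report


def select_features(table: pd.DataFrame, catalog: SubscoreCatalog,
                    criteria: SelectionCriteria | None = None) -> SelectionReport:
    """Full selection: FS pre-selection, then the dual-criterion filter.

    Features of non-selected FS are reported as excluded with reason
    ``off-FS``; the rest are filtered on assessments in the analysis EDSS
    range.
    """
    criteria = criteria or SelectionCriteria()
    fs_kept = preselect_fs(table, criteria)
    all_features = list(catalog.features())
    in_fs = [f for f in all_features if catalog.feature_fs(f) in fs_kept]
    off = [(f, "off-FS") for f in all_features if f not in in_fs]

    lo, hi = criteria.edss_range
    sub = table[table["edss"].between(lo, hi)]
    if len(sub) < 2:
        sub = table
    report = dual_criterion_filter(feature_values(sub, catalog, in_fs), criteria)
    report.excluded.extend(off)
    return report
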