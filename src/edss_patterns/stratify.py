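"""EDSS stratification and k-fold splits.

Assessments with identical EDSS are analysed together; the analysis range
4.0-6.5 in half-point steps gives six strata.  Each stratum is split into
three equal folds for cross-validation; in each iteration one fold is the
validation set and the other two form the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Stratum:
    edss_level: float
    assessments: pd.DataFrame

    @property
    def n_assessments(self) -> int:
        return len(self.assessments)

    @property
    def n_patients(self) -> int:
        return self.assessments["patient_id"].nunique()


@dataclass
class Segmentation:
    strata: list[Stratum]
    excluded: pd.DataFrame  # rows outside the range

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def segment_by_edss(features: pd.DataFrame, lo: float = 4.0, hi: float = 6.5,
                    step: float = 0.5) -> Segmentation:
    """One stratum per half-point in [lo, hi]; out-of-range rows reported."""
    if lo > hi:
        raise ValueError(f"lo {lo} exceeds hi {hi}")
    levels = [round(lo + i * step, 1) for i in range(int(round((hi - lo) / step)) + 1)]
    strata = [Stratum(level, features[features["edss"] == level].copy())
              for level in levels]
    excluded = features[~features["edss"].isin(levels)].copy()
    return Segmentation(strata, excluded)


@dataclass
class FoldSplit:
    k: int
    seed: int
    assignments: np.ndarray = field(repr=False)  # fold index per row position

    def iter_splits(self):
        """Yield (fold, train_mask, val_mask) for each CV iteration."""
        for fold in range(self.k):
            val = self.assignments == fold
            yield fold, ~val, val


def make_folds(stratum: Stratum | pd.DataFrame, k: int = 3, seed: int = 0,
               by_patient: bool = False) -> FoldSplit:
    """Random equal partition of a stratum's assessments into k folds.

    Assessment-level by default (one patient's visits may span folds, as in
    a plain three-way split); ``by_patient=True`` keeps each patient's
    visits in a single fold to rule out within-patient leakage.
    """
    df = stratum.assessments if isinstance(stratum, Stratum) else stratum
    n = len(df)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"stratum has {n} rows, fewer than k={k}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    if by_patient:
        patients = df["patient_id"].to_numpy()
        uniq = pd.unique(patients)
        order = rng.permutation(len(uniq))
        fold_of = {uniq[j]: i % k for i, j in enumerate(order)}
        assignments[:] = [fold_of[p] for p in patients]
    else:
        order = rng.permutation(n)
        assignments[order] = np.arange(n) % k  # sizes differ by at most 1
    return FoldSplit(k=k, seed=seed, assignments=assignments)
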