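"""Catalog of Neurostatus-style subscores.

The Neurostatus-EDSS protocol quantifies the neurological examination into
~120 items ("subscores"), of which 100 are mandatory at every assessment.
Each subscore belongs to one of seven Functional Systems (FS), may be
lateralized (left/right), and has a legal ordinal grade range together with
a "normal" grade (the value meaning *no deficit*, used when a deficit is
flagged as not MS-related).

The catalog also records, per subscore, the binarization threshold and the
side-merged *feature* it contributes to.  Fifteen canonical features from
the Pyramidal, Cerebellar and Sensory FS form the input space of the
clustering analysis; additional candidate features exist so that feature
selection has real work to do (near-uniform reflexes, duplicated items).

The full mandatory item list is not public; entries outside the three
analysis FS are plausible stand-ins that only need to exist structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import yaml

FS_NAMES = [
    "pyramidal",
    "cerebellar",
    "sensory",
    "brainstem",
    "visual",
    "bowel_bladder",
    "cerebral",
]

#: The 15 side-merged binary features retained by the published analysis,
#: in canonical order (used for deterministic tie-breaking everywhere).
CANONICAL_FEATURES = [
    "bmrc_upper",
    "bmrc_lower",
    "spasticity_upper",
    "spasticity_lower",
    "truncal_ataxia",
    "tremor_upper",
    "tremor_lower",
    "tandem_walking",
    "gait_ataxia",
    "romberg",
    "superficial_upper",
    "superficial_lower",
    "vibration_upper",
    "vibration_lower",
    "position_lower",
]

#: Valid EDSS values: half-point grid 0.0 .. 10.0.
EDSS_GRID = [x / 2 for x in range(0, 21)]

BMRC_NORMAL = 5  # full strength on the British Medical Research Council scale


@dataclass(frozen=True)
class Subscore:
    """One mandatory examination item.

    ``kind`` is ``"bmrc"`` for muscle-strength items, where the raw grade
    runs 0 (no contraction) to 5 (normal) and *impairment* is ``5 - grade``;
    all other items are ``"ordinal"`` with impairment equal to the grade.
    ``threshold`` lives on the impairment scale: impairment > threshold
    binarizes to 1.
    """

    id: str
    fs: str
    feature: str
    side: str  # "left" | "right" | "none"
    lo: int
    hi: int
    normal: int
    kind: str = "ordinal"
    threshold: int = 2

    def impairment(self, grade: int) -> int:
        return BMRC_NORMAL - grade if self.kind == "bmrc" else grade


class SubscoreCatalog:
    """Immutable lookup of subscores plus feature-level views."""

    def __init__(self, subscores: Iterable[Subscore]):
        self._by_id: dict[str, Subscore] = {}
        for s in subscores:
            if s.id in self._by_id:
                raise ValueError(f"duplicate subscore id {s.id!r}")
            if not (s.lo <= s.normal <= s.hi):
                raise ValueError(f"normal value of {s.id!r} outside legal range")
            self._by_id[s.id] = s

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, subscore_id: str) -> bool:
        return subscore_id in self._by_id

    def __getitem__(self, subscore_id: str) -> Subscore:
        try:
            return self._by_id[subscore_id]
        except KeyError:
            raise KeyError(f"unknown subscore {subscore_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def subscores(self) -> list[Subscore]:
        return list(self._by_id.values())

    def features(self) -> dict[str, list[Subscore]]:
        """Feature name -> contributing subscores, preserving catalog order."""
        out: dict[str, list[Subscore]] = {}
        for s in self._by_id.values():
            out.setdefault(s.feature, []).append(s)
        return out

    def feature_fs(self, feature: str) -> str:
        fss = {s.fs for s in self.features()[feature]}
        if len(fss) != 1:
            raise ValueError(f"feature {feature!r} spans multiple FS: {sorted(fss)}")
        return next(iter(fss))

    def feature_threshold(self, feature: str) -> int:
        ts = {s.threshold for s in self.features()[feature]}
        if len(ts) != 1:
            raise ValueError(f"feature {feature!r} has mixed thresholds")
        return next(iter(ts))

    def candidate_features(self, fs_whitelist: Iterable[str]) -> list[str]:
        """Features whose FS is whitelisted, in catalog order."""
        white = set(fs_whitelist)
        return [f for f in self.features() if self.feature_fs(f) in white]

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"subscores": [asdict(s) for s in self.subscores]}, fh)

    @classmethod
    def from_yaml(cls, path) -> "SubscoreCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(Subscore(**d) for d in raw["subscores"])


def _bilateral(base: str, **kw) -> list[Subscore]:
    return [
        Subscore(id=f"{base}_l", side="left", **kw),
        Subscore(id=f"{base}_r", side="right", **kw),
    ]


def default_catalog() -> SubscoreCatalog:
    """The 100 mandatory subscores used throughout this package."""
    ss: list[Subscore] = []

    # --- pyramidal (31) ---------------------------------------------------
    # Muscle strength: 4 muscle groups per limb region per side, BMRC 0-5.
    # Any muscle with impairment > 1 (BMRC <= 3) makes the region's feature high.
    for m in ["deltoid", "biceps", "triceps", "wrist_extensors"]:
        ss += _bilateral(f"bmrc_{m}", fs="pyramidal", feature="bmrc_upper",
                         lo=0, hi=5, normal=5, kind="bmrc", threshold=1)
    for m in ["hip_flexors", "knee_flexors", "knee_extensors", "foot_dorsiflexors"]:
        ss += _bilateral(f"bmrc_{m}", fs="pyramidal", feature="bmrc_lower",
                         lo=0, hi=5, normal=5, kind="bmrc", threshold=1)
    ss += _bilateral("spasticity_arm", fs="pyramidal", feature="spasticity_upper",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("spasticity_leg", fs="pyramidal", feature="spasticity_lower",
                     lo=0, hi=5, normal=0)
    for r in ["biceps", "triceps", "knee", "ankle"]:
        ss += _bilateral(f"dtr_{r}", fs="pyramidal", feature=f"dtr_{r}",
                         lo=0, hi=4, normal=1)
    ss += _bilateral("plantar_response", fs="pyramidal", feature="plantar_response",
                     lo=0, hi=2, normal=0, threshold=1)
    ss.append(Subscore("abdominal_reflexes", "pyramidal", "abdominal_reflexes",
                       "none", 0, 2, 0, threshold=1))

    # --- cerebellar (10) --------------------------------------------------
    ss += _bilateral("tremor_arm", fs="cerebellar", feature="tremor_upper",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("tremor_leg", fs="cerebellar", feature="tremor_lower",
                     lo=0, hi=5, normal=0)
    # rapid alternating movements track tremor/dysmetria almost perfectly
    ss += _bilateral("ram_arm", fs="cerebellar", feature="ram_upper",
                     lo=0, hi=5, normal=0)
    ss.append(Subscore("truncal_ataxia", "cerebellar", "truncal_ataxia", "none", 0, 4, 0))
    ss.append(Subscore("gait_ataxia", "cerebellar", "gait_ataxia", "none", 0, 5, 0))
    ss.append(Subscore("tandem_walking", "cerebellar", "tandem_walking", "none", 0, 4, 0))
    ss.append(Subscore("romberg", "cerebellar", "romberg", "none", 0, 4, 0))

    # --- sensory (19) -----------------------------------------------------
    ss += _bilateral("superficial_arm", fs="sensory", feature="superficial_upper",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("superficial_leg", fs="sensory", feature="superficial_lower",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("vibration_arm", fs="sensory", feature="vibration_upper",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("vibration_leg", fs="sensory", feature="vibration_lower",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("position_arm", fs="sensory", feature="position_upper",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("position_leg", fs="sensory", feature="position_lower",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("pain_arm", fs="sensory", feature="pain_upper",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("pain_leg", fs="sensory", feature="pain_lower",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("figure_writing", fs="sensory", feature="figure_writing",
                     lo=0, hi=4, normal=0)
    ss.append(Subscore("lhermitte", "sensory", "lhermitte", "none", 0, 1, 0, threshold=0))

    # --- visual (9) -------------------------------------------------------
    ss += _bilateral("visual_acuity", fs="visual", feature="visual_acuity",
                     lo=0, hi=5, normal=0)
    ss += _bilateral("visual_fields", fs="visual", feature="visual_fields",
                     lo=0, hi=4, normal=0)
    ss += _bilateral("disc_pallor", fs="visual", feature="disc_pallor",
                     lo=0, hi=2, normal=0, threshold=1)
    ss.append(Subscore("scotoma", "visual", "scotoma", "none", 0, 3, 0))
    ss.append(Subscore("visual_acuity_corrected", "visual", "visual_acuity_corrected",
                       "none", 0, 5, 0))
    ss.append(Subscore("pupillary_defect", "visual", "pupillary_defect", "none", 0, 2, 0,
                       threshold=1))

    # --- brainstem (16) ---------------------------------------------------
    for name, hi in [("eom_impairment", 4), ("nystagmus", 3), ("trigeminal_sensation", 4),
                     ("trigeminal_motor", 3), ("dysarthria", 5), ("dysphagia", 5),
                     ("palatal_weakness", 3), ("tongue_weakness", 3), ("vertigo", 3),
                     ("gag_reflex", 2)]:
        ss.append(Subscore(name, "brainstem", name, "none", 0, hi, 0))
    ss += _bilateral("facial_weakness", fs="brainstem", feature="facial_weakness",
                     lo=0, hi=4, normal=0)
    ss += _bilateral("hearing_loss", fs="brainstem", feature="hearing_loss",
                     lo=0, hi=4, normal=0)
    ss += _bilateral("facial_sensation", fs="brainstem", feature="facial_sensation",
                     lo=0, hi=4, normal=0)

    # --- bowel & bladder (8) ----------------------------------------------
    for name in ["urinary_hesitancy", "urinary_urgency", "urinary_incontinence",
                 "urinary_retention", "bladder_catheterisation", "bowel_incontinence",
                 "bowel_urgency", "constipation"]:
        ss.append(Subscore(name, "bowel_bladder", name, "none", 0, 4, 0))

    # --- cerebral (7) -----------------------------------------------------
    for name in ["fatigue", "depression", "euphoria", "mentation_decrease",
                 "memory_impairment", "attention_deficit", "irritability"]:
        ss.append(Subscore(name, "cerebral", name, "none", 0, 4, 0))

    cat = SubscoreCatalog(ss)
    assert len(cat) == 100, f"catalog has {len(cat)} subscores, expected 100"
    return cat
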