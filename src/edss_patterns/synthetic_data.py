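"""Synthetic assessment-cohort generator with planted disability archetypes.

Emulates the structure of a large SPMS trial cohort (≈1600 patients, ≈8
visits each, EDSS mass concentrated on 6.0/6.5) so the whole pipeline runs
and is testable without clinical data.  Each assessment draws an EDSS
stratum, then a latent *archetype* — a subset of the 15 canonical features
that are impaired ("high") for that assessment.  Archetypes are the planted
ground truth the clustering should recover; they are stored in a reserved
``truth_`` column that analysis stages must ignore.

Subscore grades are sampled uniformly within the archetype's high/low grade
ranges (clipped so high grades always binarize to 1 and low grades to 0),
with symmetric ±1 grade noise, left/right agreement with probability
``side_correlation``, and optional per-assessment dropout of designated-high
features (which keeps within-group feature correlations at realistic,
sub-0.7 levels in the study-scale configuration).

The generator makes no attempt at longitudinal within-patient dynamics:
EDSS and archetype are drawn independently per visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .catalog import (CANONICAL_FEATURES, EDSS_GRID, FS_NAMES, SubscoreCatalog,
                      default_catalog)
from .ingest import (TRUTH_PREFIX, fss_column, pt_column, schema_columns,
                     subscore_column)
from .patterns import DEFAULT_GROUPS


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class Archetype:
    """A latent impairment profile: which canonical features are high."""

    name: str
    high_features: tuple[str, ...]
    high_grade_range: tuple[int, int] = (3, 4)  # impairment scale, inclusive
    low_grade_range: tuple[int, int] = (0, 2)


@dataclass
class GeneratorConfig:
    n_patients: int
    visits_per_patient_mean: float
    visits_per_patient_sd: float
    edss_stratum_weights: dict[float, float]
    archetypes: list[Archetype]
    archetype_weights_per_stratum: dict[float, list[float]]
    grade_noise: float = 0.05
    pt_label_rate: float = 0.02
    side_correlation: float = 0.7
    #: Probability a designated-high feature is sampled low for one assessment.
    feature_dropout: float = 0.0
    seed: int = 0

    def validate(self, catalog: SubscoreCatalog | None = None) -> None:
        catalog = catalog or default_catalog()
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ["grade_noise", "pt_label_rate", "side_correlation",
                     "feature_dropout"]:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        w = np.array(list(self.edss_stratum_weights.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ConfigError("edss_stratum_weights must be a probability vector")
        for level in self.edss_stratum_weights:
            if level not in EDSS_GRID:
                raise ConfigError(f"EDSS level {level} not on the half-point grid")
        for level, vec in self.archetype_weights_per_stratum.items():
            v = np.array(vec, dtype=float)
            if len(v) != len(self.archetypes):
                raise ConfigError(f"archetype weights for EDSS {level} have "
                                  f"{len(v)} entries, expected {len(self.archetypes)}")
            if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise ConfigError(f"archetype weights for EDSS {level} not a "
                                  "probability vector")
        for level in self.edss_stratum_weights:
            if self.edss_stratum_weights[level] > 0 \
                    and level not in self.archetype_weights_per_stratum:
                raise ConfigError(f"no archetype weights for EDSS {level}")
        feats = catalog.features()
        for a in self.archetypes:
            for f in a.high_features:
                if f not in CANONICAL_FEATURES:
                    raise ConfigError(f"archetype {a.name}: {f!r} is not one of "
                                      "the 15 canonical features")
                t = catalog.feature_threshold(f)
                hi_lo, hi_hi = _effective_range(a.high_grade_range, t, feats[f], high=True)
                lo_lo, lo_hi = _effective_range(a.low_grade_range, t, feats[f], high=False)
                if hi_lo > hi_hi or lo_lo > lo_hi:
                    raise ConfigError(f"archetype {a.name}: grade ranges "
                                      f"incompatible with threshold of {f}")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {plain(k): plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        data = plain(asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["archetypes"] = [
            Archetype(name=a["name"], high_features=tuple(a["high_features"]),
                      high_grade_range=tuple(a.get("high_grade_range", (3, 4))),
                      low_grade_range=tuple(a.get("low_grade_range", (0, 2))))
            for a in data["archetypes"]]
        data["edss_stratum_weights"] = {
            float(k): float(v) for k, v in data["edss_stratum_weights"].items()}
        data["archetype_weights_per_stratum"] = {
            float(k): list(map(float, v))
            for k, v in data["archetype_weights_per_stratum"].items()}
        return cls(**data)


def _effective_range(rng_pair, threshold, subs, high: bool) -> tuple[int, int]:
    """Clip an archetype grade range (impairment scale) to honour the threshold."""
    max_imp = min(5 - s.lo if s.kind == "bmrc" else s.hi for s in subs)
    lo, hi = rng_pair
    if high:
        return max(lo, threshold + 1), min(hi, max_imp)
    return max(lo, 0), min(hi, threshold)


def _sample_feature_values(rng, high_mask, arch_idx, archetypes, threshold, subs):
    """Per-row impairment target for one feature, archetype range aware."""
    n = len(high_mask)
    vals = np.zeros(n, dtype=int)
    for ai, a in enumerate(archetypes):
        rows = arch_idx == ai
        if not rows.any():
            continue
        for status, pair in ((True, a.high_grade_range), (False, a.low_grade_range)):
            lo, hi = _effective_range(pair, threshold, subs, high=status)
            mask = rows & (high_mask == status)
            if mask.any():
                vals[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return vals


def generate_cohort(config: GeneratorConfig,
                    catalog: SubscoreCatalog | None = None) -> pd.DataFrame:
    """One row per visit, in the assessment CSV schema plus truth columns."""
    catalog = catalog or default_catalog()
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)

    # patients and visit counts (normal, rounded, clipped at >= 1)
    nv = np.rint(rng.normal(config.visits_per_patient_mean,
                            config.visits_per_patient_sd,
                            config.n_patients)).astype(int)
    nv = np.clip(nv, 1, None)
    n = int(nv.sum())
    patient_ids = np.repeat([f"P{i:05d}" for i in range(config.n_patients)], nv)
    visit_index = np.concatenate([np.arange(k) for k in nv])
    age = np.clip(np.rint(rng.normal(48.0, 7.9, config.n_patients)), 18, 75)
    sex = np.where(rng.random(config.n_patients) < 0.60, "female", "male")

    # per-assessment EDSS stratum and archetype
    levels = np.array(sorted(config.edss_stratum_weights), dtype=float)
    probs = np.array([config.edss_stratum_weights[l] for l in levels])
    edss = rng.choice(levels, size=n, p=probs / probs.sum())
    arch_idx = np.zeros(n, dtype=int)
    n_arch = len(config.archetypes)
    for level in levels:
        rows = np.flatnonzero(edss == level)
        if len(rows):
            w = np.array(config.archetype_weights_per_stratum[float(level)])
            arch_idx[rows] = rng.choice(n_arch, size=len(rows), p=w / w.sum())

    # which canonical features are high per assessment
    high_by_arch = np.zeros((n_arch, len(CANONICAL_FEATURES)), dtype=bool)
    for ai, a in enumerate(config.archetypes):
        for f in a.high_features:
            high_by_arch[ai, CANONICAL_FEATURES.index(f)] = True

    cols: dict[str, np.ndarray] = {}
    feats = catalog.features()
    for j, fname in enumerate(CANONICAL_FEATURES):
        subs = feats[fname]
        t = catalog.feature_threshold(fname)
        high = high_by_arch[arch_idx, j]
        if config.feature_dropout > 0:
            high = high & (rng.random(n) >= config.feature_dropout)
        v_left = _sample_feature_values(rng, high, arch_idx, config.archetypes, t, subs)
        v_right = _sample_feature_values(rng, high, arch_idx, config.archetypes, t, subs)
        same = rng.random(n) < config.side_correlation
        v_right = np.where(same, v_left, v_right)

        sides = {"left": v_left, "right": v_right, "none": v_left}
        by_side: dict[str, list] = {}
        for s in subs:
            by_side.setdefault(s.side, []).append(s)
        for side, side_subs in by_side.items():
            imp = sides[side]
            if side_subs[0].kind == "bmrc":
                # one randomly chosen carrier muscle realizes the impairment
                carrier = rng.integers(0, len(side_subs), size=n)
                for k, s in enumerate(side_subs):
                    g = np.full(n, 5)
                    g[carrier == k] = 5 - imp[carrier == k]
                    cols[subscore_column(s.id)] = g
            else:
                for s in side_subs:
                    cols[subscore_column(s.id)] = np.clip(imp, s.lo, s.hi)

    # candidate features destined for exclusion by the dual criterion:
    # near-duplicates of canonical items ...
    for src, dst in [("tremor_arm_l", "ram_arm_l"), ("tremor_arm_r", "ram_arm_r"),
                     ("superficial_arm_l", "pain_arm_l"), ("superficial_arm_r", "pain_arm_r"),
                     ("superficial_leg_l", "pain_leg_l"), ("superficial_leg_r", "pain_leg_r")]:
        cols[subscore_column(dst)] = cols[subscore_column(src)].copy()
    # ... and near-constant items (reflexes, rarely-abnormal sensory tests);
    # bilateral ones are mirrored left/right, as reflex findings usually are
    near_uniform = {
        "position_arm_l": 0.95, "figure_writing_l": 0.95, "lhermitte": 0.93,
        "dtr_biceps_l": 0.93, "dtr_triceps_l": 0.93, "dtr_knee_l": 0.93,
        "dtr_ankle_l": 0.93, "plantar_response_l": 0.93,
        "abdominal_reflexes": 0.90,
    }
    for sid, p0 in near_uniform.items():
        s = catalog[sid]
        base = np.full(n, s.normal)
        odd = rng.random(n) >= p0
        base[odd] = rng.integers(s.lo, s.hi + 1, size=int(odd.sum()))
        cols[subscore_column(sid)] = base
        if sid.endswith("_l"):
            cols[subscore_column(sid[:-2] + "_r")] = base.copy()

    # remaining (non-analysis FS) items: mostly normal, mild when not
    for s in catalog.subscores:
        col = subscore_column(s.id)
        if col in cols:
            continue
        u = rng.random(n)
        g = np.zeros(n, dtype=int)
        g[u >= 0.90] = 1
        g[u >= 0.98] = min(2, s.hi)
        cols[col] = np.clip(g + s.normal, s.lo, s.hi)

    # symmetric +-1 grade noise, clipped to each legal range
    if config.grade_noise > 0:
        for s in catalog.subscores:
            col = subscore_column(s.id)
            flip = rng.random(n) < config.grade_noise
            sign = rng.integers(0, 2, size=n) * 2 - 1
            cols[col] = np.clip(cols[col] + flip * sign, s.lo, s.hi)

    # P/T labels (deficits not attributed to MS)
    for s in catalog.subscores:
        lab = np.full(n, "", dtype=object)
        hit = rng.random(n) < config.pt_label_rate
        lab[hit] = np.where(rng.random(int(hit.sum())) < 0.5, "P", "T")
        cols[pt_column(s.id)] = lab

    # FSS: maximum implied subscore severity within each FS, clipped to 0-6
    for fs in FS_NAMES:
        members = [s for s in catalog.subscores if s.fs == fs]
        imp = np.stack([5 - cols[subscore_column(s.id)] if s.kind == "bmrc"
                        else cols[subscore_column(s.id)] for s in members])
        cols[fss_column(fs)] = np.clip(imp.max(axis=0), 0, 6)

    table = pd.DataFrame({
        "patient_id": patient_ids,
        "visit_index": visit_index,
        "visit_month": visit_index * 3,  # nominal quarterly schedule
        "age": np.repeat(age, nv),
        "sex": np.repeat(sex, nv),
        "edss": edss,
        "ambulation_score": _ambulation_for_edss(edss),
        **cols,
    })
    table[TRUTH_PREFIX + "archetype"] = [config.archetypes[i].name for i in arch_idx]
    return table[schema_columns(catalog) + [TRUTH_PREFIX + "archetype"]]


def _ambulation_for_edss(edss: np.ndarray) -> np.ndarray:
    """Stratum-consistent Ambulation Score (0-12): walking capacity drives
    EDSS above 4.0, so the map is a fixed staircase."""
    bounds = [(4.0, 1), (4.5, 2), (5.0, 3), (5.5, 4), (6.0, 6), (6.5, 7),
              (7.0, 8), (7.5, 9), (8.0, 10), (8.5, 11), (9.0, 12)]
    out = np.zeros(len(edss), dtype=int)
    for level, score in bounds:
        out[edss >= level] = score
    return out


# ---------------------------------------------------------------------------
# study-scale default configuration


def default_archetypes() -> list[Archetype]:
    """Four archetypes mirroring the pattern groups A-D."""
    return [
        Archetype("motor_cerebellar", DEFAULT_GROUPS["A"]),
        Archetype("spastic_tandem", DEFAULT_GROUPS["B"]),
        Archetype("sensory_romberg", DEFAULT_GROUPS["C"]),
        Archetype("ambulation_only", ()),
    ]


def planted_config(n_assessments: int = 900, edss: float = 6.0,
                   weights: tuple[float, ...] = (0.30, 0.25, 0.25, 0.20),
                   grade_noise: float = 0.05, seed: int = 0) -> GeneratorConfig:
    """Single-stratum cohort with the four disjoint archetypes planted at
    known mixing weights: one visit per patient, no feature dropout.

    The configuration recovery tests run on: cluster labels should match the
    ``truth_archetype`` column up to noise-induced ambiguity.
    """
    w = np.array(weights, dtype=float)
    return GeneratorConfig(
        n_patients=n_assessments,
        visits_per_patient_mean=1.0,
        visits_per_patient_sd=0.0,
        edss_stratum_weights={edss: 1.0},
        archetypes=default_archetypes(),
        archetype_weights_per_stratum={edss: list(w / w.sum())},
        grade_noise=grade_noise,
        pt_label_rate=0.0,
        side_correlation=0.7,
        feature_dropout=0.0,
        seed=seed,
    )


def default_expandlike_config(n_patients: int = 1636, seed: int = 0) -> GeneratorConfig:
    """Study-scale configuration: 1636 patients, 8 ± 2.97 visits.

    EDSS stratum weights put ≈86% of assessments in 4.0-6.5 with the mode at
    6.0, matching the published per-stratum assessment counts; archetype
    mixing weights per stratum follow the published full-data pattern
    distribution (A rising with EDSS, D vanishing by 6.5).
    """
    counts_in_range = {4.0: 1038, 4.5: 1172, 5.0: 831, 5.5: 948,
                      6.0: 3900, 6.5: 3346}
    counts_outside = {0.0: 10, 0.5: 15, 1.0: 40, 1.5: 60, 2.0: 120, 2.5: 160,
                      3.0: 230, 3.5: 330, 7.0: 480, 7.5: 250, 8.0: 120, 8.5: 53}
    total = sum(counts_in_range.values()) + sum(counts_outside.values())
    weights = {lvl: c / total
               for lvl, c in sorted({**counts_in_range, **counts_outside}.items())}
    # renormalize exactly
    s = sum(weights.values())
    weights = {lvl: w / s for lvl, w in weights.items()}

    mix_in_range = {
        4.0: [0.306, 0.323, 0.108, 0.263],
        4.5: [0.517, 0.226, 0.055, 0.202],
        5.0: [0.532, 0.204, 0.060, 0.204],
        5.5: [0.499, 0.317, 0.056, 0.128],
        6.0: [0.754, 0.200, 0.000, 0.046],
        6.5: [0.975, 0.025, 0.000, 0.000],
    }
    mix = {}
    for lvl in weights:
        if lvl in mix_in_range:
            vec = mix_in_range[lvl]
        elif lvl <= 2.0:
            vec = [0.05, 0.05, 0.20, 0.70]
        elif lvl <= 3.5:
            vec = [0.15, 0.20, 0.20, 0.45]
        else:  # 7.0 and above
            vec = [0.90, 0.10, 0.00, 0.00]
        v = np.array(vec, dtype=float)
        mix[lvl] = list(v / v.sum())

    return GeneratorConfig(
        n_patients=n_patients,
        visits_per_patient_mean=8.0,
        visits_per_patient_sd=2.97,
        edss_stratum_weights=weights,
        archetypes=default_archetypes(),
        archetype_weights_per_stratum=mix,
        grade_noise=0.05,
        pt_label_rate=0.02,
        side_correlation=0.7,
        feature_dropout=0.25,
        seed=seed,
    )
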