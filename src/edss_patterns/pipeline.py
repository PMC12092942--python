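"""End-to-end orchestration: ingest → pre-process → select → binarize →
stratify → cluster → patterns, in full-data and cross-validated modes.

``run_full`` tunes once per EDSS stratum on all of its assessments;
``run_cv`` repeats tuning inside each training split and applies the
trained model to the held-out fold, mirroring the full/train/validation
layout of the published distribution table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binarize import BinarizationSpec, binarize_table, feature_columns
from .catalog import SubscoreCatalog, default_catalog
from .cluster_engine import small_grid, tune, apply_model
from .feature_select import SelectionCriteria, select_features
from .ingest import adjust_pt_labels, describe, read_assessments
from .patterns import PatternRuleSet, assign_pattern, pattern_distribution, \
    profile_clusters
from .stratify import make_folds, segment_by_edss
from .synthetic_data import GeneratorConfig, generate_cohort

log = logging.getLogger("edss_patterns")


@dataclass
class RunConfig:
    #: either a generator configuration or a path to an assessment CSV
    generator: GeneratorConfig | None = None
    input_csv: str | Path | None = None
    catalog: SubscoreCatalog = field(default_factory=default_catalog)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    rules: PatternRuleSet = field(default_factory=PatternRuleSet)
    edss_range: tuple[float, float] = (4.0, 6.5)
    cv_k: int = 3
    cv_seed: int = 0
    cluster_seed: int = 0
    #: explicit (EmbedParams, ClusterParams) list; None -> compact per-stratum grid
    grid: list | None = None
    #: strata with fewer assessments are skipped with a warning
    min_stratum_size: int = 60
    out_dir: str | Path | None = None

    def __post_init__(self):
        if (self.generator is None) == (self.input_csv is None):
            raise ValueError("provide exactly one of generator / input_csv")


def _load(config: RunConfig) -> pd.DataFrame:
    if config.generator is not None:
        return generate_cohort(config.generator, config.catalog)
    return read_assessments(config.input_csv, config.catalog)


def _prepare(config: RunConfig):
    """Shared front half: ingest, P/T adjustment, descriptives, selection,
    binarization, stratification."""
    table = _load(config)
    log.info("ingest: %d assessments", len(table))
    table = adjust_pt_labels(table, config.catalog)
    summary = describe(table)
    report = select_features(table, config.catalog, config.criteria)
    log.info("selection: %d features retained", len(report.retained))
    spec = BinarizationSpec(catalog=config.catalog, features=report.retained)
    features = binarize_table(table, spec)
    seg = segment_by_edss(features, *config.edss_range)
    log.info("stratification: %d strata, %d excluded rows",
             len(seg.strata), seg.n_excluded)
    return table, summary, report, features, seg


def _stratum_grid(config: RunConfig, n_rows: int):
    if config.grid is not None:
        return config.grid
    return small_grid(n_rows, seed=config.cluster_seed)


def _profiles_payload(profiles, rules):
    return [{"cluster": p.cluster_id, "n": p.n_assessments,
             "pattern": assign_pattern(p, rules),
             "percent_high": {k: round(v, 2) for k, v in p.percent_high.items()}}
            for p in profiles]


def run_full(config: RunConfig) -> dict:
    """Tune and cluster every stratum on all of its assessments."""
    table, summary, sel, features, seg = _prepare(config)
    rules = config.rules
    strata_out: dict = {}
    dist_rows = []
    labels_frames = []
    skipped = []
    for st in seg.strata:
        if st.n_assessments < config.min_stratum_size:
            skipped.append({"edss": st.edss_level, "n": st.n_assessments})
            log.warning("stratum %.1f skipped (n=%d)", st.edss_level,
                        st.n_assessments)
            continue
        model = tune(st.assessments, _stratum_grid(config, st.n_assessments))
        profiles = profile_clusters(st.assessments, model.labels)
        dist = pattern_distribution(st.assessments, model.labels, rules)
        dist_rows.append(dist.assign(mode="full"))
        lab = st.assessments[["patient_id", "visit_index", "edss"]].copy()
        lab["cluster"] = model.labels
        labels_frames.append(lab)
        strata_out[str(st.edss_level)] = {
            "n_assessments": st.n_assessments,
            "n_patients": st.n_patients,
            "embed_params": dataclasses.asdict(model.embed_params),
            "cluster_params": dataclasses.asdict(model.cluster_params),
            "relative_validity": model.relative_validity,
            "n_clusters": model.n_clusters,
            "noise_fraction": model.noise_fraction,
            "score_table": model.score_table.to_dict("records"),
            "profiles": _profiles_payload(profiles, rules),
            "distribution": dist.reset_index().to_dict("records"),
        }
    report = {
        "mode": "full",
        "software": {"edss_patterns": __version__},
        "seeds": {"cluster": config.cluster_seed, "cv": config.cv_seed,
                  "generator": getattr(config.generator, "seed", None)},
        "descriptive": summary.to_dict(),
        "selection": sel.to_dict(),
        "excluded_rows": seg.n_excluded,
        "skipped_strata": skipped,
        "strata": strata_out,
    }
    _write_outputs(config, report, dist_rows, labels_frames)
    return report


def run_cv(config: RunConfig) -> dict:
    """Per stratum: k-fold split, tune on training folds, apply to validation."""
    table, summary, sel, features, seg = _prepare(config)
    rules = config.rules
    strata_out: dict = {}
    dist_rows = []
    skipped = []
    for st in seg.strata:
        if st.n_assessments < max(config.min_stratum_size, config.cv_k):
            skipped.append({"edss": st.edss_level, "n": st.n_assessments})
            log.warning("stratum %.1f skipped (n=%d)", st.edss_level,
                        st.n_assessments)
            continue
        split = make_folds(st, k=config.cv_k, seed=config.cv_seed)
        iters = []
        for fold, train_mask, val_mask in split.iter_splits():
            train = st.assessments[train_mask]
            val = st.assessments[val_mask]
            model = tune(train, _stratum_grid(config, len(train)))
            val_labels = apply_model(model, val)
            train_dist = pattern_distribution(train, model.labels, rules)
            val_dist = pattern_distribution(val, val_labels, rules)
            dist_rows.append(train_dist.assign(mode=f"train{fold}"))
            dist_rows.append(val_dist.assign(mode=f"val{fold}"))
            iters.append({
                "fold": fold,
                "n_train": len(train), "n_val": len(val),
                "embed_params": dataclasses.asdict(model.embed_params),
                "cluster_params": dataclasses.asdict(model.cluster_params),
                "relative_validity": model.relative_validity,
                "n_clusters": model.n_clusters,
                "train_distribution": train_dist.reset_index().to_dict("records"),
                "val_distribution": val_dist.reset_index().to_dict("records"),
            })
        strata_out[str(st.edss_level)] = {
            "n_assessments": st.n_assessments,
            "n_patients": st.n_patients,
            "iterations": iters,
        }
    report = {
        "mode": "cv",
        "software": {"edss_patterns": __version__},
        "seeds": {"cluster": config.cluster_seed, "cv": config.cv_seed,
                  "generator": getattr(config.generator, "seed", None)},
        "descriptive": summary.to_dict(),
        "selection": sel.to_dict(),
        "excluded_rows": seg.n_excluded,
        "skipped_strata": skipped,
        "strata": strata_out,
    }
    _write_outputs(config, report, dist_rows, [])
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_outputs(config: RunConfig, report: dict, dist_rows, labels_frames):
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=2)
    if dist_rows:
        pd.concat(dist_rows).reset_index().to_csv(
            out / "table6_distribution.csv", index=False)
    for frame in labels_frames:
        level = frame["edss"].iloc[0]
        frame.to_csv(out / f"labels_{level}.csv", index=False)
    for level, payload in report["strata"].items():
        if "profiles" in payload:
            rows = [{"cluster": p["cluster"], "n": p["n"], "pattern": p["pattern"],
                     **p["percent_high"]} for p in payload["profiles"]]
            pd.DataFrame(rows).to_csv(out / f"table4_profiles_{level}.csv",
                                      index=False)
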