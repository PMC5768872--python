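"""End-to-end pipeline: filter -> features -> platelet ID -> overlap ->
classification -> shrinkage sensitivity -> Mantel -> rarefaction.

A single YAML/dict configuration drives the run; one global seed is split
deterministically into per-stage substreams, every report carries the config
digest and seed, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import TrainingConfig, build_training_set, run_classification
from .io import config_digest, write_features, write_measurements, write_report
from .mantel import anatomical_distance, mantel, morph_distance
from .measurements import (FEATURE_NAMES, Sample, compute_feature_table,
                           pooled_points, samples_to_table, validate_and_filter)
from .morphospace import overlap_matrix, rarefy_variance
from .platelet import build_reference, call_platelet, partition_for_classification
from .simulate import (PLATELET_CLASSES, SlabConfig, default_class_models,
                       simulate_library, simulate_slab)
from .taphonomy import ShrinkageScenario, sensitivity_report

logger = logging.getLogger(__name__)

#: allowed configuration keys (nested); unknown keys are a validation error
_SCHEMA: dict[str, Any] = {
    "seed": None,
    "log_level": None,
    "out_dir": None,
    "simulate": {
        "library": {"n_samples_per_class": None, "n_meas_per_sample": None,
                    "sample_effect_sd": None},
        "slab": {"n_locations": None, "extent_mm": None, "correlation_length_mm": None,
                 "field_sd": None, "n_platelet": None, "base_class": None,
                 "platelet_class": None, "n_meas_per_location": None},
    },
    "paths": {"measurements": None, "library": None},
    "params": {
        "min_measurements": None,
        "hdr_level": None,
        "alpha": None,
        "dataset_ids": None,
        "priors": None,
        "grid_nx": None,
        "grid_ny": None,
        "permutations": None,
        "shrinkage_d": None,
        "rarefaction_sizes": None,
        "rarefaction_reps": None,
    },
}


def validate_config(config: dict, schema: Optional[dict] = None, prefix: str = "") -> None:
    schema = _SCHEMA if schema is None else schema
    for key, value in config.items():
        if key not in schema:
            raise ValueError(f"unknown configuration key: {prefix + key!r}")
        if isinstance(value, dict) and isinstance(schema[key], dict):
            validate_config(value, schema[key], prefix + key + ".")


def demo_config(seed: int = 0) -> dict:
    """Self-contained demo: simulate the library and slab, run every stage."""
    return {
        "seed": seed,
        "simulate": {
            "library": {"n_samples_per_class": 15, "n_meas_per_sample": 30},
            "slab": {"n_locations": 53, "n_platelet": 21,
                     "correlation_length_mm": 40.0,
                     "n_meas_per_location": 40},
        },
        "params": {
            "hdr_level": 0.95,
            "alpha": 0.05,
            "dataset_ids": [1, 2, 3, 4, 5, 6],
            "grid_nx": 121,
            "grid_ny": 121,
            "permutations": 999,
            "shrinkage_d": 0.20,
            "rarefaction_sizes": [10, 25, 50, 100, 200],
            "rarefaction_reps": 200,
        },
    }


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text()) or {}
    validate_config(config)
    return config


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute every stage and write per-stage outputs plus a provenance
    manifest under ``out_dir``.  A stage failure halts the run; outputs of
    completed stages remain on disk and the manifest marks the failure."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = config.get("params", {})
    min_meas = int(params.get("min_measurements", 5))
    digest = config_digest(config)
    manifest: dict[str, Any] = {
        "version": __version__, "seed": seed, "config_digest": digest,
        "stages_completed": [], "failed_stage": None,
    }

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        logger.info("stage complete: %s", name)

    try:
        # --- inputs: simulate or load -----------------------------------
        models = default_class_models()
        if "simulate" in config:
            sim = config["simulate"]
            library = simulate_library(
                list(models.values()),
                seed=_stage_seed(seed, 0),
                **{k: v for k, v in sim.get("library", {}).items()},
            )
            slab_cfg = SlabConfig(seed=_stage_seed(seed, 1),
                                  **{k: tuple(v) if k == "extent_mm" else v
                                     for k, v in sim.get("slab", {}).items()})
            fossil = simulate_slab(slab_cfg, models)
            write_measurements(library, out / "library.csv")
            write_measurements(fossil, out / "measurements.csv")
        else:
            from .io import read_samples
            paths = config.get("paths", {})
            library = read_samples(paths["library"], min_meas).samples
            fossil_res = read_samples(paths["measurements"], min_meas)
            fossil = fossil_res.samples
        finish_stage("inputs")

        # --- filter + features ------------------------------------------
        vres = validate_and_filter(samples_to_table(fossil), min_measurements=min_meas)
        fossil = vres.feature_ready
        fossil_feats = compute_feature_table(fossil, min_measurements=min_meas)
        lib_feats = compute_feature_table(library, min_measurements=min_meas)
        write_features(fossil_feats, out / "features_fossil.csv")
        write_features(lib_feats, out / "features_library.csv")
        finish_stage("features")

        # --- platelet identification ------------------------------------
        hdr = float(params.get("hdr_level", 0.95))
        non_platelet_ref = pooled_points(
            [s for s in library if s.colour_label not in PLATELET_CLASSES]
        )
        reference = build_reference(non_platelet_ref, hdr_level=hdr)
        calls = [call_platelet(s, reference, seed=_stage_seed(seed, 2)) for s in fossil]
        partition = partition_for_classification(calls, fossil)
        write_report(
            {"calls": {c.sample_id: {
                "verdict": c.verdict,
                "criterion_i_outside_morphospace": c.criterion_i_outside_morphospace,
                "criterion_ii_image_evidence": c.criterion_ii_image_evidence,
                "outside_fraction": round(c.outside_fraction, 6),
                "n_platelet_measurements": c.n_platelet_measurements,
            } for c in calls},
             "hdr_level": hdr},
            out / "platelet_calls.json", config=config, seed=seed)
        finish_stage("platelet_id")

        # --- morphospace overlap ----------------------------------------
        groups = {"fossil": pooled_points(fossil)}
        for label in models:
            pts = pooled_points([s for s in library if s.colour_label == label])
            if len(pts):
                groups[label] = pts
        ov = overlap_matrix(groups, nx=int(params.get("grid_nx", 151)),
                            ny=int(params.get("grid_ny", 151)))
        write_report({"overlap": {a: {b: round(v, 6) for b, v in row.items()}
                                  for a, row in ov.items()}},
                     out / "overlap.json", config=config, seed=seed)
        finish_stage("overlap")

        # --- colour classification --------------------------------------
        alpha = float(params.get("alpha", 0.05))
        priors = params.get("priors", "equal")
        classification: dict[str, Any] = {}
        for ds in params.get("dataset_ids", [1]):
            tc = TrainingConfig(int(ds))
            fossil_in = fossil
            if tc.shrinkage_corrected:
                from .taphonomy import apply_correction
                d = float(params.get("shrinkage_d", 0.20))
                fossil_in = apply_correction(fossil, ShrinkageScenario(d))
            training = build_training_set(
                library, fossil_in, tc,
                non_platelet_fossil=partition.non_platelet_samples,
                min_measurements=min_meas)
            selection, model, report, predictions = run_classification(
                training, alpha=alpha, priors=priors)
            classification[f"dataset_{ds}"] = {
                "retained_variables": selection.retained,
                "eliminated": [[v, round(p, 6)] for v, p in selection.eliminated],
                "self_test_accuracy": round(report.self_test_accuracy, 6),
                "loo_accuracy": round(report.loo_accuracy, 6),
                "confusion": report.confusion,
                "fossil_predictions": predictions.round(6),
            }
        write_report(classification, out / "classification.json",
                     config=config, seed=seed)
        finish_stage("classification")

        # --- shrinkage sensitivity --------------------------------------
        d = float(params.get("shrinkage_d", 0.20))
        sens = sensitivity_report(fossil, library, [ShrinkageScenario(d)],
                                  hdr_level=hdr, seed=_stage_seed(seed, 3),
                                  grid_nx=81, grid_ny=81)
        write_report({
            "baseline_overlap": {k: round(v, 6) for k, v in
                                 sens.baseline.overlap_with_groups.items()},
            "scenarios": [{
                "d": s.d,
                "overlap": {k: round(v, 6) for k, v in s.overlap_with_groups.items()},
                "changed_platelet_calls": sens.changed_platelet_calls[s.d],
            } for s in sens.scenarios],
        }, out / "sensitivity.json", config=config, seed=seed)
        finish_stage("sensitivity")

        # --- spatial autocorrelation (Mantel) ---------------------------
        if all(s.slab_xy is not None for s in fossil) and len(fossil) >= 4:
            dm = morph_distance(fossil_feats[list(FEATURE_NAMES)])
            da = anatomical_distance(fossil)
            res = mantel(dm, da, n_permutations=int(params.get("permutations", 999)),
                         seed=_stage_seed(seed, 4))
            write_report({"mantel": {"r": round(res.r, 6), "p": res.p,
                                     "n_permutations": res.n_permutations}},
                         out / "mantel.json", config=config, seed=seed)
        finish_stage("mantel")

        # --- rarefaction of variance ------------------------------------
        pts = pooled_points(fossil)
        sizes = params.get("rarefaction_sizes")
        if sizes is None:
            sizes = sorted({max(2, len(pts) // k) for k in (20, 10, 4, 2, 1)})
        sizes = [int(s) for s in sizes if int(s) <= len(pts)] + [len(pts)]
        curve = rarefy_variance(pts, sorted(set(sizes)),
                                n_reps=int(params.get("rarefaction_reps", 200)),
                                seed=_stage_seed(seed, 5))
        write_report({"rarefaction": {
            "sizes": list(curve.sizes),
            "mean": [round(v, 4) for v in curve.mean],
            "lower": [round(v, 4) for v in curve.lower],
            "upper": [round(v, 4) for v in curve.upper],
            "full_value": round(curve.full_value, 4),
        }}, out / "rarefaction.json", config=config, seed=seed)
        finish_stage("rarefaction")
    except Exception as exc:
        manifest["failed_stage"] = {
            "after": manifest["stages_completed"][-1] if manifest["stages_completed"] else None,
            "error": str(exc),
        }
        write_report(manifest, out / "manifest.json", config=config, seed=seed)
        raise
    write_report(manifest, out / "manifest.json", config=config, seed=seed)
    return out
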