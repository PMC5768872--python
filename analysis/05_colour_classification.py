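#!/usr/bin/env python
"""Colour classification of the fossil samples under all six training-set
configurations: backward stepwise variable selection, QDA fit, self-test and
leave-one-out validation, and per-sample colour predictions."""

from pathlib import Path

from melanomorph.classify import TrainingConfig, build_training_set, run_classification
from melanomorph.io import read_samples, write_report
from melanomorph.measurements import pooled_points
from melanomorph.platelet import (build_reference, call_platelet,
                                  partition_for_classification)
from melanomorph.simulate import PLATELET_CLASSES
from melanomorph.taphonomy import ShrinkageScenario, apply_correction

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    library = read_samples(ROOT / "data" / "library.csv").feature_ready
    slab = read_samples(ROOT / "data" / "slab.csv").feature_ready
    ref_pts = pooled_points(
        [s for s in library if s.colour_label not in PLATELET_CLASSES])
    reference = build_reference(ref_pts, hdr_level=0.95)
    calls = [call_platelet(s, reference, seed=SEED) for s in slab]
    partition = partition_for_classification(calls, slab)

    payload = {}
    for ds in range(1, 7):
        config = TrainingConfig(ds)
        fossil_in = slab
        if config.shrinkage_corrected:
            fossil_in = apply_correction(slab, ShrinkageScenario(0.20))
        training = build_training_set(
            library, fossil_in, config,
            non_platelet_fossil=partition.non_platelet_samples)
        selection, model, report, pred = run_classification(training)
        counts = pred["predicted_colour"].value_counts().to_dict()
        print(f"dataset {ds}: retained {selection.retained}")
        print(f"  self-test {report.self_test_accuracy:.3f}, "
              f"LOO {report.loo_accuracy:.3f}; fossil predictions {counts}")
        payload[f"dataset_{ds}"] = {
            "retained_variables": selection.retained,
            "self_test_accuracy": round(report.self_test_accuracy, 6),
            "loo_accuracy": round(report.loo_accuracy, 6),
            "fossil_predictions": pred.round(6),
        }
    write_report(payload, ROOT / "classification.json", seed=SEED)
    print(f"reports -> {ROOT / 'classification.json'}")


if __name__ == "__main__":
    main()
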