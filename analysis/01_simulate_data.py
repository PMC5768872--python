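#!/usr/bin/env python
"""Generate the study data sets: an extant training library of seven colour
classes and a fossil slab of 53 sampling locations, 21 of them in contiguous
platelet-bearing body regions.  Writes measurement tables under results/data/.
"""

from pathlib import Path

from melanomorph.io import write_measurements
from melanomorph.simulate import (SlabConfig, default_class_models,
                                  simulate_library, simulate_slab)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    models = default_class_models()
    library = simulate_library(list(models.values()), n_samples_per_class=15,
                               n_meas_per_sample=30, seed=SEED)
    slab = simulate_slab(SlabConfig(seed=SEED + 1), models)
    write_measurements(library, OUT / "library.csv")
    write_measurements(slab, OUT / "slab.csv")
    n_platelet = sum(s.stacking_evidence for s in slab)
    print(f"library: {len(library)} samples across {len(models)} colour classes")
    print(f"slab: {len(slab)} locations, {n_platelet} with platelet image evidence")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
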