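#!/usr/bin/env python
"""Validate the measurement tables (body-cavity exclusion, axis swaps,
minimum counts) and compute the eight-feature summary per sample."""

from pathlib import Path

from melanomorph.io import read_samples, write_features
from melanomorph.measurements import compute_feature_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name in ("library", "slab"):
        res = read_samples(ROOT / "data" / f"{name}.csv")
        feats = compute_feature_table(res.feature_ready)
        write_features(feats, ROOT / f"features_{name}.csv")
        print(f"{name}: {res.n_input_rows} rows -> {len(res.samples)} samples "
              f"({res.n_body_cavity_rows} body-cavity rows dropped, "
              f"{res.n_swapped_rows} axis swaps, "
              f"{len(res.excluded_small_samples)} samples below minimum count)")
        print(f"  features -> {ROOT / f'features_{name}.csv'}")


if __name__ == "__main__":
    main()
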