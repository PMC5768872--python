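#!/usr/bin/env python
"""Spatial structure of the slab: Mantel permutation test relating
morphological similarity to anatomical proximity, and rarefaction of
variance to assess sampling adequacy."""

from pathlib import Path

from melanomorph.io import read_samples, write_report
from melanomorph.mantel import anatomical_distance, mantel, morph_distance
from melanomorph.measurements import (FEATURE_NAMES, compute_feature_table,
                                      pooled_points)
from melanomorph.morphospace import rarefy_variance

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    slab = read_samples(ROOT / "data" / "slab.csv").feature_ready
    feats = compute_feature_table(slab)[list(FEATURE_NAMES)]
    res = mantel(morph_distance(feats), anatomical_distance(slab),
                 n_permutations=999, seed=SEED)
    print(f"Mantel test: r = {res.r:.3f}, p = {res.p:.3g} "
          f"({res.n_permutations} permutations)")

    pts = pooled_points(slab)
    sizes = sorted({max(2, len(pts) // k) for k in (40, 20, 10, 4, 2)}) + [len(pts)]
    curve = rarefy_variance(pts, sizes, n_reps=500, seed=SEED)
    print("rarefaction of variance (size: mean [2.5%, 97.5%]):")
    for s, m, lo, hi in zip(curve.sizes, curve.mean, curve.lower, curve.upper):
        print(f"  {s:5d}: {m:12.1f} [{lo:12.1f}, {hi:12.1f}]")
    write_report({
        "mantel": {"r": round(res.r, 6), "p": res.p,
                   "n_permutations": res.n_permutations},
        "rarefaction": {"sizes": list(curve.sizes),
                        "mean": [round(v, 2) for v in curve.mean],
                        "lower": [round(v, 2) for v in curve.lower],
                        "upper": [round(v, 2) for v in curve.upper]},
    }, ROOT / "spatial.json", seed=SEED)
    print(f"report -> {ROOT / 'spatial.json'}")


if __name__ == "__main__":
    main()
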