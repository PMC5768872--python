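"""Mantel permutation test: are nanostructures in nearby slab regions more
similar than those from distant regions?

Morphological distance is Euclidean distance between z-scored feature
vectors; anatomical distance is either Euclidean millimetre distance on the
slab coordinates or shortest-path hop count on a body-region adjacency
graph.  The test statistic is the Pearson correlation of the strictly-lower
triangles; the null distribution comes from simultaneous row/column
permutation of one matrix, and the one-sided p-value is
(1 + #{r_perm >= r_obs}) / (1 + n_permutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .measurements import Sample


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    alternative: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r out of [-1, 1]")


def morph_distance(features: pd.DataFrame) -> np.ndarray:
    """Euclidean distance between z-scored per-sample feature vectors."""
    if features.isna().any().any():
        bad = features.index[features.isna().any(axis=1)].tolist()
        raise ValueError(f"samples missing features: {bad}")
    X = features.to_numpy(dtype=float)
    sd = X.std(0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(0)) / sd
    return squareform(pdist(Z))


def anatomical_distance(
    samples: Sequence[Sample],
    adjacency: Optional[Mapping[str, Sequence[str]]] = None,
) -> np.ndarray:
    """Pairwise anatomical distance between sampling locations.

    With slab coordinates: Euclidean mm distance.  With a body-region
    adjacency mapping: shortest-path hop counts between regions (breadth-
    first search; no heavier graph machinery is warranted for hop counts).
    """
    if adjacency is not None:
        return _hop_distance(samples, adjacency)
    has_xy = [s.slab_xy is not None for s in samples]
    if not all(has_xy):
        if any(has_xy):
            raise ValueError("mixed coordinate availability: some samples lack slab_xy")
        raise ValueError("no slab coordinates; supply an adjacency mapping instead")
    coords = np.array([s.slab_xy for s in samples], dtype=float)
    return squareform(pdist(coords))


def _hop_distance(samples: Sequence[Sample], adjacency: Mapping[str, Sequence[str]]) -> np.ndarray:
    regions = sorted({r for r in adjacency} | {n for vs in adjacency.values() for n in vs})
    hops: dict[str, dict[str, int]] = {}
    for start in regions:
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adjacency.get(node, ()):  # undirected: also reverse edges
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
                for other, nbs in adjacency.items():
                    if node in nbs and other not in dist:
                        dist[other] = dist[node] + 1
                        nxt.append(other)
            frontier = nxt
        hops[start] = dist
    n = len(samples)
    out = np.zeros((n, n))
    for i, si in enumerate(samples):
        for j, sj in enumerate(samples):
            if i == j:
                continue
            try:
                out[i, j] = hops[si.body_region][sj.body_region]
            except KeyError:
                raise ValueError(
                    f"no adjacency path between regions "
                    f"{si.body_region!r} and {sj.body_region!r}"
                ) from None
    return out


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} has a nonzero diagonal")
    return d


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    One-sided ('greater', the default — nearby means more similar) or
    two-sided by |r|.  The permutation null relabels the objects of the
    second matrix, permuting its rows and columns together.
    """
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 objects")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    tril = np.tril_indices(n, k=-1)
    v1 = d1[tril]
    if np.ptp(v1) == 0 or np.ptp(d2[tril]) == 0:
        raise ValueError("constant lower triangle: correlation undefined")
    v1c = v1 - v1.mean()
    v1n = v1c / np.linalg.norm(v1c)

    def corr_with(mat: np.ndarray) -> float:
        v = mat[tril]
        vc = v - v.mean()
        return float(v1n @ (vc / np.linalg.norm(vc)))

    r_obs = corr_with(d2)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = corr_with(d2[np.ix_(perm, perm)])
        if alternative == "greater":
            exceed += r_perm >= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (1 + exceed) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations,
                        seed=seed, alternative=alternative)


def mantel_exhaustive(d1: np.ndarray, d2: np.ndarray, alternative: str = "greater") -> MantelResult:
    """Exact Mantel p-value by full enumeration of all n! relabelings
    (feasible only for small n; used as an oracle for the sampled test)."""
    from itertools import permutations

    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    n = d1.shape[0]
    if n > 8:
        raise ValueError("exhaustive enumeration limited to n <= 8")
    tril = np.tril_indices(n, k=-1)
    v1 = d1[tril]
    v1c = v1 - v1.mean()
    v1n = v1c / np.linalg.norm(v1c)

    def corr_with(mat: np.ndarray) -> float:
        v = mat[tril]
        vc = v - v.mean()
        return float(v1n @ (vc / np.linalg.norm(vc)))

    r_obs = corr_with(d2)
    count = 0
    total = math.factorial(n)
    for perm in permutations(range(n)):
        r_perm = corr_with(d2[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_perm >= r_obs - 1e-12
        else:
            count += abs(r_perm) >= abs(r_obs) - 1e-12
    return MantelResult(r=r_obs, p=count / total, n_permutations=total - 1,
                        seed=0, alternative=alternative)
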