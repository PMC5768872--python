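"""Two-dimensional morphospace: kernel densities, proportional overlap,
centroid-distance dispersion comparison, and rarefaction of variance.

Densities of (length, diameter) measurements are estimated with a Gaussian
product kernel on a shared grid, converted to proportions by dividing by their
sum, and compared by the proportional-overlap statistic: the sum over grid
nodes of the pointwise minimum of two proportion densities.  Overlap is 1 for
identical distributions and 0 for disjoint ones.  Comparability requires that
every group's density is built on the same grid with the same bandwidth,
estimated once from the pooled data of all groups including the fossil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid over morphospace (x = length, y = diameter)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 151
    ny: int = 151

    def __post_init__(self) -> None:
        if self.nx < 32 or self.ny < 32:
            raise ValueError("grid must have at least 32 nodes per axis")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("grid ranges must be non-degenerate")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.ny)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (
            (p[:, 0] >= self.x_min) & (p[:, 0] <= self.x_max)
            & (p[:, 1] >= self.y_min) & (p[:, 1] <= self.y_max)
        )

    @classmethod
    def from_points(
        cls,
        points: np.ndarray,
        bandwidth: Sequence[float],
        pad_bandwidths: float = 3.0,
        nx: int = 151,
        ny: int = 151,
    ) -> "GridSpec":
        """Grid spanning the pooled points, padded by ``pad_bandwidths``
        bandwidths per side so kernel mass is not clipped."""
        p = np.asarray(points, dtype=float)
        hx, hy = float(bandwidth[0]), float(bandwidth[1])
        return cls(
            x_min=float(p[:, 0].min() - pad_bandwidths * hx),
            x_max=float(p[:, 0].max() + pad_bandwidths * hx),
            y_min=float(p[:, 1].min() - pad_bandwidths * hy),
            y_max=float(p[:, 1].max() + pad_bandwidths * hy),
            nx=nx,
            ny=ny,
        )


@dataclass(frozen=True)
class MorphospaceDensity:
    """Proportion-normalized density on a grid: values sum to 1."""

    grid: GridSpec
    bandwidth: tuple[float, float]
    values: np.ndarray  # (nx, ny)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("values shape does not match grid")
        if np.any(v < 0):
            raise ValueError("density values must be non-negative")
        if abs(float(v.sum()) - 1.0) > 1e-9:
            raise ValueError("density values must sum to 1")


@dataclass(frozen=True)
class OverlapResult:
    group_a: str
    group_b: str
    overlap: float
    grid: GridSpec
    bandwidth: tuple[float, float]

    def __post_init__(self) -> None:
        if not -1e-12 <= self.overlap <= 1 + 1e-12:
            raise ValueError("overlap must lie in [0, 1]")


def silverman_bandwidth_1d(x: np.ndarray, d: int = 2) -> float:
    """Normal-reference (Silverman) bandwidth for one axis of a d-dimensional
    product-kernel density: h = sigma_robust * (4 / ((d + 2) n))^(1/(d+4)),
    with sigma_robust = min(SD, IQR/1.349)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    if sigma <= 0:
        raise ValueError("zero spread: bandwidth undefined")
    return sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def shared_bandwidth(pooled_points: np.ndarray) -> np.ndarray:
    """Per-axis Silverman bandwidth from the pooled data of every group to be
    compared (including the fossil); reuse verbatim for each group's density."""
    p = np.asarray(pooled_points, dtype=float)
    if len(p) < 10:
        raise ValueError(f"need >= 10 pooled points for bandwidth estimation, got {len(p)}")
    return np.array([silverman_bandwidth_1d(p[:, 0]), silverman_bandwidth_1d(p[:, 1])])


def kde_pdf(points: np.ndarray, bandwidth: Sequence[float], query: np.ndarray) -> np.ndarray:
    """Gaussian product-kernel density of ``points`` evaluated at ``query``
    (true pdf scale, integrates to 1 over the plane)."""
    pts = np.asarray(points, dtype=float)
    q = np.atleast_2d(np.asarray(query, dtype=float))
    hx, hy = float(bandwidth[0]), float(bandwidth[1])
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive")
    out = np.empty(len(q))
    norm = 1.0 / (2.0 * np.pi * hx * hy * len(pts))
    chunk = max(1, int(2e7) // max(len(pts), 1))
    for start in range(0, len(q), chunk):
        block = q[start : start + chunk]
        zx = (block[:, 0, None] - pts[None, :, 0]) / hx
        zy = (block[:, 1, None] - pts[None, :, 1]) / hy
        out[start : start + len(block)] = norm * np.exp(-0.5 * (zx**2 + zy**2)).sum(1)
    return out


def fit_density(
    points: np.ndarray,
    grid: GridSpec,
    bandwidth: Sequence[float],
) -> MorphospaceDensity:
    """Gaussian-kernel density of the points on the grid, normalized to a
    proportion (sums to 1).

    Points outside the grid range are an error: their kernel mass would be
    silently truncated, biasing overlap comparisons — re-fit the grid instead.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(p) < 3:
        raise ValueError("need at least 3 points for a density")
    hx, hy = float(bandwidth[0]), float(bandwidth[1])
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive")
    inside = grid.contains(p)
    if not inside.all():
        raise ValueError(
            f"{int((~inside).sum())} points fall outside the grid range; "
            "re-fit the grid (GridSpec.from_points) to cover all groups"
        )
    # separable kernel: values[i,j] = sum_n kx(x_i - L_n) * ky(y_j - D_n)
    kx = np.exp(-0.5 * ((grid.x[:, None] - p[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((grid.y[:, None] - p[None, :, 1]) / hy) ** 2)
    values = kx @ ky.T
    total = values.sum()
    if total <= 0:
        raise ValueError("density mass vanished on grid; bandwidth too small for grid spacing")
    return MorphospaceDensity(grid=grid, bandwidth=(hx, hy), values=values / total)


def density_from_grid_values(grid: GridSpec, values: np.ndarray,
                             bandwidth: Sequence[float] = (1.0, 1.0)) -> MorphospaceDensity:
    """Wrap explicit non-negative grid values (e.g. an analytic density
    evaluated on the grid) as a proportion-normalized MorphospaceDensity."""
    v = np.asarray(values, dtype=float)
    return MorphospaceDensity(grid=grid, bandwidth=(float(bandwidth[0]), float(bandwidth[1])),
                              values=v / v.sum())


def proportional_overlap(a: MorphospaceDensity, b: MorphospaceDensity,
                         group_a: str = "a", group_b: str = "b") -> OverlapResult:
    """Sum over grid nodes of min(a, b) on proportion densities.

    Requires identical grid and bandwidth; anything else is a silent
    apples-to-oranges comparison and raises.
    """
    if a.grid != b.grid:
        raise ValueError("densities computed on different grids")
    if a.bandwidth != b.bandwidth:
        raise ValueError("densities computed with different bandwidths")
    overlap = float(np.minimum(a.values, b.values).sum())
    return OverlapResult(group_a=group_a, group_b=group_b,
                         overlap=min(overlap, 1.0), grid=a.grid, bandwidth=a.bandwidth)


def overlap_matrix(
    points_by_group: Mapping[str, np.ndarray],
    nx: int = 151,
    ny: int = 151,
    bandwidth: Optional[Sequence[float]] = None,
) -> dict[str, dict[str, float]]:
    """Pairwise proportional overlaps on a shared grid and bandwidth.

    The bandwidth defaults to the Silverman rule on the pooled points of all
    groups; the grid spans the pooled range padded by 3 bandwidths."""
    pooled = np.vstack([np.asarray(v, float) for v in points_by_group.values()])
    bw = np.asarray(bandwidth, float) if bandwidth is not None else shared_bandwidth(pooled)
    grid = GridSpec.from_points(pooled, bw, nx=nx, ny=ny)
    densities = {k: fit_density(v, grid, bw) for k, v in points_by_group.items()}
    keys = list(points_by_group)
    return {
        ka: {
            kb: proportional_overlap(densities[ka], densities[kb], ka, kb).overlap
            for kb in keys
        }
        for ka in keys
    }


@dataclass(frozen=True)
class CentroidDistanceResult:
    """One-way comparison of within-group dispersion via distances to the
    group centroid in z-scored (length, diameter) space."""

    group_mean_distance: dict[str, float]
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def centroid_distance_test(
    points_by_group: Mapping[str, np.ndarray],
    standardize: bool = True,
) -> CentroidDistanceResult:
    """Test whether multivariate distance from the group mean centroid varies
    between groups (a dispersion comparison).

    Each observation's Euclidean distance to its own group centroid is
    computed in per-axis z-scored space (pooled SD, so the nm length scale
    does not dominate the diameter axis), then a one-way linear model of
    distance on group membership gives the F test.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in points_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 observations")
    if standardize:
        pooled = np.vstack(list(groups.values()))
        mu, sd = pooled.mean(0), pooled.std(0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        groups = {k: (v - mu) / sd for k, v in groups.items()}
    distances = {
        k: np.linalg.norm(v - v.mean(0), axis=1) for k, v in groups.items()
    }
    f, p = stats.f_oneway(*distances.values())
    n_total = sum(len(v) for v in distances.values())
    return CentroidDistanceResult(
        group_mean_distance={k: float(v.mean()) for k, v in distances.items()},
        f_statistic=float(f),
        p_value=float(p),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
    )


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean and quantile band of a variance statistic under subsampling."""

    sizes: tuple[int, ...]
    mean: np.ndarray
    lower: np.ndarray   # 2.5% quantile
    upper: np.ndarray   # 97.5% quantile
    full_value: float
    n_reps: int
    seed: int


def total_variance(points: np.ndarray) -> float:
    """Trace of the (length, diameter) sample covariance (n-1 denominator)."""
    p = np.asarray(points, dtype=float)
    return float(np.trace(np.cov(p.T, ddof=1)))


def rarefy_variance(
    points: np.ndarray,
    sizes: Sequence[int],
    n_reps: int = 1000,
    seed: int = 0,
    statistic=total_variance,
) -> RarefactionCurve:
    """Rarefaction of variance: does the variance statistic stabilize before
    the achieved sample size?

    For each subsample size s < n, draws ``n_reps`` subsamples without
    replacement and summarizes the statistic; at s = n the curve equals the
    full-sample value exactly with zero spread.
    """
    p = np.asarray(points, dtype=float)
    n = len(p)
    sizes = tuple(int(s) for s in sizes)
    if any(s < 2 for s in sizes):
        raise ValueError("subsample sizes must be >= 2")
    if max(sizes) > n:
        raise ValueError(f"max size {max(sizes)} exceeds n = {n}")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    full = float(statistic(p))
    mean = np.empty(len(sizes))
    lower = np.empty(len(sizes))
    upper = np.empty(len(sizes))
    for i, s in enumerate(sizes):
        if s == n:
            mean[i] = lower[i] = upper[i] = full
            continue
        vals = np.array([
            statistic(p[rng.choice(n, size=s, replace=False)]) for _ in range(n_reps)
        ])
        mean[i] = vals.mean()
        lower[i], upper[i] = np.quantile(vals, [0.025, 0.975])
    return RarefactionCurve(sizes=sizes, mean=mean, lower=lower, upper=upper,
                            full_value=full, n_reps=n_reps, seed=seed)
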