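"""Two-criterion platelet identification with a clustering fallback.

A sample is called platelet-bearing when (i) its measurements fall outside
the extant avian morphospace built from non-platelet melanosomes, and (ii)
independent image evidence (overlapping mouldic nanostructures or flattened
3D platelets) is present.  Criterion (ii) is an input flag — it was assessed
by eye on electron micrographs and image analysis is out of scope here.

"Outside morphospace" is operationalized with the highest-density region
(HDR) of a kernel density fitted to the non-platelet reference: a measurement
is outside when its reference density falls below the threshold delimiting
the ``hdr_level`` highest-density region, and the sample-level flag is true
when more than half the measurements are outside.  When the two criteria
disagree the sample is treated as mixed and a two-component Gaussian mixture
on (log length, log diameter) splits its measurements; the component whose
centroid sits in lower reference density is labelled platelet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .measurements import Sample
from .morphospace import kde_pdf, silverman_bandwidth_1d

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceMorphospace:
    """Non-platelet reference KDE with its HDR density threshold."""

    points: np.ndarray          # (n, 2) reference (length, diameter)
    bandwidth: tuple[float, float]
    hdr_level: float
    density_threshold: float    # density below this is outside the HDR

    def density(self, query: np.ndarray) -> np.ndarray:
        return kde_pdf(self.points, self.bandwidth, query)

    def outside(self, query: np.ndarray) -> np.ndarray:
        return self.density(query) < self.density_threshold


@dataclass(frozen=True)
class PlateletCall:
    sample_id: str
    verdict: str                          # platelet | non_platelet | mixed
    criterion_i_outside_morphospace: bool
    criterion_ii_image_evidence: bool
    outside_fraction: float
    measurement_platelet_flags: np.ndarray  # (n,) bool, per measurement
    hdr_level: float

    def __post_init__(self) -> None:
        if self.verdict not in ("platelet", "non_platelet", "mixed"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        ci, cii = self.criterion_i_outside_morphospace, self.criterion_ii_image_evidence
        if self.verdict == "platelet" and not (ci and cii):
            raise ValueError("verdict=platelet requires both criteria true")
        if self.verdict == "non_platelet" and (ci or cii):
            raise ValueError("verdict=non_platelet requires both criteria false")

    @property
    def n_platelet_measurements(self) -> int:
        return int(self.measurement_platelet_flags.sum())


def build_reference(
    reference_points: np.ndarray,
    hdr_level: float = 0.95,
    bandwidth: Optional[Sequence[float]] = None,
) -> ReferenceMorphospace:
    """Fit the non-platelet reference KDE and locate its HDR threshold.

    The threshold is the (1 - hdr_level) quantile of the reference density
    evaluated at the reference points themselves: by construction roughly
    that fraction of reference-distributed points falls below it.
    """
    pts = np.asarray(reference_points, dtype=float)
    if len(pts) < 50:
        raise ValueError(f"reference needs >= 50 measurements, got {len(pts)}")
    if not 0.0 < hdr_level < 1.0:
        raise ValueError("hdr_level must be in (0, 1)")
    if bandwidth is None:
        bandwidth = (silverman_bandwidth_1d(pts[:, 0]), silverman_bandwidth_1d(pts[:, 1]))
    dens = kde_pdf(pts, bandwidth, pts)
    threshold = float(np.quantile(dens, 1.0 - hdr_level))
    return ReferenceMorphospace(
        points=pts,
        bandwidth=(float(bandwidth[0]), float(bandwidth[1])),
        hdr_level=hdr_level,
        density_threshold=threshold,
    )


def morphospace_exclusion(
    sample: Sample,
    reference: ReferenceMorphospace,
    majority: float = 0.5,
) -> tuple[bool, np.ndarray, float]:
    """Criterion (i): does the sample fall outside the reference morphospace?

    Returns (sample_flag, per-measurement outside flags, outside fraction);
    the sample flag is true when the outside fraction exceeds ``majority``.
    """
    pts = sample.points()
    if len(pts) == 0:
        raise ValueError(f"sample {sample.sample_id!r} has no measurements")
    outside = reference.outside(pts)
    frac = float(outside.mean())
    return frac > majority, outside, frac


def call_platelet(
    sample: Sample,
    reference: ReferenceMorphospace,
    majority: float = 0.5,
    seed: int = 0,
) -> PlateletCall:
    """Apply the two-criterion rule; cluster when the criteria disagree.

    Both criteria true -> platelet (all measurements flagged); both false ->
    non-platelet.  Ambiguous/mixed samples are split by a seeded 2-component
    Gaussian mixture on log axes; members of the component whose centroid has
    lower reference density are flagged as platelets.  A non-converged
    mixture falls back to the per-measurement HDR flags with a warning.
    """
    if sample.stacking_evidence is None:
        raise ValueError(
            f"sample {sample.sample_id!r}: stacking_evidence flag required "
            "for platelet identification"
        )
    crit_i, outside, frac = morphospace_exclusion(sample, reference, majority)
    crit_ii = bool(sample.stacking_evidence)
    n = sample.n_measurements

    if crit_i and crit_ii:
        return PlateletCall(sample.sample_id, "platelet", True, True, frac,
                            np.ones(n, dtype=bool), reference.hdr_level)
    if not crit_i and not crit_ii:
        return PlateletCall(sample.sample_id, "non_platelet", False, False, frac,
                            np.zeros(n, dtype=bool), reference.hdr_level)

    flags = _cluster_platelet_flags(sample, reference, outside, seed)
    return PlateletCall(sample.sample_id, "mixed", crit_i, crit_ii, frac,
                        flags, reference.hdr_level)


def _cluster_platelet_flags(
    sample: Sample,
    reference: ReferenceMorphospace,
    outside: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Split an ambiguous sample: 2-component Gaussian mixture on
    (log length, log diameter); the component centred in lower reference
    density is the platelet sub-population."""
    pts = sample.points()
    if len(pts) < 4:
        logger.warning("sample %s too small to cluster; using HDR flags", sample.sample_id)
        return outside.copy()
    logpts = np.log(pts)
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         random_state=seed, n_init=3)
    try:
        labels = gm.fit_predict(logpts)
        converged = bool(gm.converged_)
    except (ValueError, np.linalg.LinAlgError):
        converged = False
    if not converged:
        logger.warning("sample %s: mixture fit did not converge; "
                       "falling back to per-measurement HDR flags", sample.sample_id)
        return outside.copy()
    centroids = np.exp(gm.means_)            # back to nm
    cent_dens = reference.density(centroids)
    platelet_component = int(np.argmin(cent_dens))
    return labels == platelet_component


@dataclass
class Partition:
    """Exhaustive, disjoint split of measurements for colour classification."""

    non_platelet_samples: list[Sample]   # feed the colour classifier
    platelet_samples: list[Sample]       # platelet-flagged measurements only


def partition_for_classification(
    calls: Iterable[PlateletCall],
    samples: Sequence[Sample],
) -> Partition:
    """Remove platelet-flagged measurements from the classifier stream.

    Platelet samples move entirely to the platelet side; mixed samples
    contribute only their non-platelet measurements to the classifier.
    """
    by_id = {c.sample_id: c for c in calls}
    missing = [s.sample_id for s in samples if s.sample_id not in by_id]
    if missing:
        raise ValueError(f"platelet calls missing for samples: {missing}")
    non_platelet: list[Sample] = []
    platelet: list[Sample] = []
    for s in samples:
        call = by_id[s.sample_id]
        flags = call.measurement_platelet_flags
        if len(flags) != s.n_measurements:
            raise ValueError(f"flag length mismatch for sample {s.sample_id!r}")
        keep = [m for m, f in zip(s.measurements, flags) if not f]
        drop = [m for m, f in zip(s.measurements, flags) if f]
        if keep:
            non_platelet.append(s.with_measurements(keep))
        if drop:
            platelet.append(s.with_measurements(drop))
    if not non_platelet:
        logger.warning("all measurements platelet-flagged: classifier stream is empty")
    return Partition(non_platelet_samples=non_platelet, platelet_samples=platelet)
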