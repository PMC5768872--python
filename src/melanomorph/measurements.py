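"""Domain types for nanostructure measurement data and per-sample feature vectors.

A *measurement* is one melanosome (or melanosome mold) measured in the image
plane: long-axis length and short-axis diameter, both in nanometres.  A
*sample* is one sampling location — a patch on a fossil slab or an extant
feather — holding many measurements plus metadata.  Eight summary statistics
per sample (means, coefficients of variation and skews of length, diameter
and aspect ratio) form the feature vector consumed by the colour classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SOURCES = ("fossil", "extant")

COLOUR_LABELS = (
    "black",
    "brown",
    "grey",
    "iridescent",
    "platelet_iridescence",
    "hummingbird_platelet",
    "penguin_brown_black",
    "unknown",
)

#: canonical order of the eight per-sample predictors
FEATURE_NAMES = (
    "length_mean",
    "length_cv",
    "diameter_mean",
    "diameter_cv",
    "aspect_ratio_mean",
    "aspect_ratio_skew",
    "length_skew",
    "diameter_skew",
)

#: features that carry nm units (everything else is dimensionless)
DIMENSIONAL_FEATURES = ("length_mean", "diameter_mean")

MANDATORY_COLUMNS = ("sample_id", "length_nm", "diameter_nm")

#: full measurement-table schema, in writing order
TABLE_COLUMNS = (
    "sample_id",
    "taxon",
    "source",
    "body_region",
    "slab_x_mm",
    "slab_y_mm",
    "colour_label",
    "near_body_cavity",
    "stacking_evidence",
    "length_nm",
    "diameter_nm",
)


@dataclass(frozen=True)
class NanostructureMeasurement:
    """One measured organelle or mold: long axis (length) and short axis
    (diameter) in the image plane, nanometres."""

    length: float
    diameter: float

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.diameter > 0):
            raise ValueError(
                f"measurement axes must be positive, got "
                f"length={self.length}, diameter={self.diameter}"
            )
        if self.length < self.diameter:
            raise ValueError(
                f"length ({self.length}) < diameter ({self.diameter}); "
                "swap axes before constructing"
            )

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.diameter


@dataclass
class Sample:
    """A sampling location with its measurements and metadata."""

    sample_id: str
    source: str = "extant"
    taxon: str = ""
    body_region: str = ""
    slab_xy: Optional[tuple[float, float]] = None
    colour_label: Optional[str] = None
    near_body_cavity: bool = False
    stacking_evidence: Optional[bool] = None
    measurements: list[NanostructureMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.colour_label is not None and self.colour_label not in COLOUR_LABELS:
            raise ValueError(f"unknown colour_label {self.colour_label!r}")

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    def lengths(self) -> np.ndarray:
        return np.array([m.length for m in self.measurements], dtype=float)

    def diameters(self) -> np.ndarray:
        return np.array([m.diameter for m in self.measurements], dtype=float)

    def points(self) -> np.ndarray:
        """(n, 2) array of (length, diameter) pairs in nm."""
        return np.column_stack([self.lengths(), self.diameters()]) if self.measurements else np.empty((0, 2))

    def with_measurements(self, measurements: Sequence[NanostructureMeasurement]) -> "Sample":
        return replace(self, measurements=list(measurements))


@dataclass(frozen=True)
class FeatureVector:
    """The eight per-sample predictors."""

    length_mean: float
    length_cv: float
    diameter_mean: float
    diameter_cv: float
    aspect_ratio_mean: float
    aspect_ratio_skew: float
    length_skew: float
    diameter_skew: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature value: {self.as_dict()}")
        if self.length_cv < 0 or self.diameter_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.aspect_ratio_mean < 1:
            raise ValueError(
                f"mean aspect ratio {self.aspect_ratio_mean} < 1; "
                "length/diameter axes are inconsistent"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class ValidationResult:
    """Outcome of table validation: retained samples plus an itemized account
    of everything that was dropped or repaired."""

    samples: list[Sample]
    n_input_rows: int
    n_body_cavity_rows: int
    n_swapped_rows: int
    rejected_rows: list[int]              # 0-based row indices with non-positive axes
    excluded_small_samples: dict[str, int]  # sample_id -> n_measurements (< minimum)

    @property
    def feature_ready(self) -> list[Sample]:
        """Samples meeting the minimum measurement count."""
        excluded = set(self.excluded_small_samples)
        return [s for s in self.samples if s.sample_id not in excluded]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if pd.isna(value) or value == "":
        return False
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes", "t")
    return bool(value)


def _parse_opt_bool(value) -> Optional[bool]:
    if value is None or (not isinstance(value, str) and pd.isna(value)) or value == "":
        return None
    return _parse_bool(value)


def validate_and_filter(
    raw_rows: pd.DataFrame,
    min_measurements: int = 5,
) -> ValidationResult:
    """Validate a measurement table and assemble :class:`Sample` objects.

    Rows flagged as measured near internal organs / the body cavity are
    excluded before any analysis.  Rows with non-positive axes are rejected.
    Rows with length < diameter have the two values swapped (axis assignment
    in manual image measurement is error-prone) with a logged warning.
    Samples with fewer than ``min_measurements`` retained measurements are
    kept in the output but reported as excluded from feature computation.

    Raises ``ValueError`` for a missing mandatory column or a duplicated
    (sample_id, measurement_index) pair when an explicit index column is
    present.
    """
    for col in MANDATORY_COLUMNS:
        if col not in raw_rows.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    if "measurement_index" in raw_rows.columns:
        dup = raw_rows.duplicated(subset=["sample_id", "measurement_index"])
        if dup.any():
            pairs = raw_rows.loc[dup, ["sample_id", "measurement_index"]].iloc[0]
            raise ValueError(
                "duplicate (sample_id, measurement_index): "
                f"({pairs['sample_id']!r}, {pairs['measurement_index']!r})"
            )

    n_input = len(raw_rows)
    n_cavity = 0
    n_swapped = 0
    rejected: list[int] = []
    by_sample: dict[str, Sample] = {}

    for pos, (_, row) in enumerate(raw_rows.iterrows()):
        if _parse_bool(row.get("near_body_cavity", False)):
            n_cavity += 1
            continue
        length = float(row["length_nm"])
        diameter = float(row["diameter_nm"])
        if not (length > 0 and diameter > 0) or not np.isfinite(length) or not np.isfinite(diameter):
            rejected.append(pos)
            logger.warning("row %d rejected: non-positive axes (%s, %s)", pos, length, diameter)
            continue
        if length < diameter:
            length, diameter = diameter, length
            n_swapped += 1
            logger.warning(
                "row %d: length < diameter; axes swapped to (%s, %s)", pos, length, diameter
            )
        sid = str(row["sample_id"])
        if sid not in by_sample:
            xy = None
            if "slab_x_mm" in row.index and pd.notna(row.get("slab_x_mm")) and str(row.get("slab_x_mm")) != "":
                xy = (float(row["slab_x_mm"]), float(row["slab_y_mm"]))
            label = row.get("colour_label")
            label = None if (label is None or (not isinstance(label, str) and pd.isna(label)) or label == "") else str(label)
            by_sample[sid] = Sample(
                sample_id=sid,
                source=str(row.get("source", "extant") or "extant"),
                taxon=str(row.get("taxon", "") or ""),
                body_region=str(row.get("body_region", "") or ""),
                slab_xy=xy,
                colour_label=label,
                near_body_cavity=False,
                stacking_evidence=_parse_opt_bool(row.get("stacking_evidence")),
            )
        by_sample[sid].measurements.append(NanostructureMeasurement(length, diameter))

    small = {
        s.sample_id: s.n_measurements
        for s in by_sample.values()
        if s.n_measurements < min_measurements
    }
    for sid, n in small.items():
        logger.info("sample %s excluded from feature computation: %d < %d measurements",
                    sid, n, min_measurements)
    if n_cavity:
        logger.info("%d rows excluded: near body cavity", n_cavity)

    return ValidationResult(
        samples=list(by_sample.values()),
        n_input_rows=n_input,
        n_body_cavity_rows=n_cavity,
        n_swapped_rows=n_swapped,
        rejected_rows=rejected,
        excluded_small_samples=small,
    )


def _skew(values: np.ndarray) -> float:
    """Fisher-Pearson standardized third moment (no small-sample bias
    correction); 0 for degenerate (zero-variance) input."""
    if np.std(values) == 0:
        return 0.0
    return float(stats.skew(values, bias=True))


def compute_features(sample: Sample, min_measurements: int = 5) -> FeatureVector:
    """Compute the eight-feature summary of a sample.

    Means are arithmetic; CV is the n-1 sample standard deviation over the
    mean; aspect ratio is averaged over per-measurement length/diameter
    ratios; skewness is the moment (Fisher-Pearson) estimator.  Samples in
    which every measurement is identical get CV = 0 and skew = 0 with a
    warning.
    """
    n = sample.n_measurements
    if n < min_measurements:
        raise ValueError(
            f"sample {sample.sample_id!r} has {n} measurements; "
            f"minimum for feature computation is {min_measurements}"
        )
    lengths = sample.lengths()
    diameters = sample.diameters()
    ratios = lengths / diameters

    def cv(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.mean(x))

    if np.std(lengths) == 0 and np.std(diameters) == 0:
        warnings.warn(
            f"sample {sample.sample_id!r}: all measurements identical; "
            "CV and skew set to 0",
            stacklevel=2,
        )

    return FeatureVector(
        length_mean=float(np.mean(lengths)),
        length_cv=cv(lengths),
        diameter_mean=float(np.mean(diameters)),
        diameter_cv=cv(diameters),
        aspect_ratio_mean=float(np.mean(ratios)),
        aspect_ratio_skew=_skew(ratios),
        length_skew=_skew(lengths),
        diameter_skew=_skew(diameters),
    )


def compute_feature_table(
    samples: Iterable[Sample],
    min_measurements: int = 5,
    group_by: str = "sample",
) -> pd.DataFrame:
    """Feature table: one row per group (default: per sample).

    ``group_by='taxon'`` pools measurements across samples of the same taxon
    before summarizing, for libraries where the unit of analysis is the
    species rather than the patch.
    """
    if group_by not in ("sample", "taxon"):
        raise ValueError("group_by must be 'sample' or 'taxon'")
    groups: dict[str, list[Sample]]
    if group_by == "sample":
        groups = {s.sample_id: [s] for s in samples}
    else:
        groups = {}
        for s in samples:
            groups.setdefault(s.taxon or s.sample_id, []).append(s)

    records = []
    for key, members in groups.items():
        pooled = members[0].with_measurements(
            [m for s in members for m in s.measurements]
        )
        if pooled.n_measurements < min_measurements:
            continue
        fv = compute_features(pooled, min_measurements=min_measurements)
        rec: dict = {"sample_id": key}
        rec.update(fv.as_dict())
        rec["n_measurements"] = pooled.n_measurements
        head = members[0]
        rec["source"] = head.source
        rec["taxon"] = head.taxon
        rec["body_region"] = head.body_region
        rec["colour_label"] = head.colour_label
        if head.slab_xy is not None:
            rec["slab_x_mm"], rec["slab_y_mm"] = head.slab_xy
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    if not df.empty:
        df = df.set_index("sample_id")
    return df


def samples_to_table(samples: Iterable[Sample]) -> pd.DataFrame:
    """Flatten samples to the canonical measurement-table schema."""
    rows = []
    for s in samples:
        for m in s.measurements:
            rows.append({
                "sample_id": s.sample_id,
                "taxon": s.taxon,
                "source": s.source,
                "body_region": s.body_region,
                "slab_x_mm": s.slab_xy[0] if s.slab_xy else "",
                "slab_y_mm": s.slab_xy[1] if s.slab_xy else "",
                "colour_label": s.colour_label or "",
                "near_body_cavity": s.near_body_cavity,
                "stacking_evidence": "" if s.stacking_evidence is None else s.stacking_evidence,
                "length_nm": m.length,
                "diameter_nm": m.diameter,
            })
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def pooled_points(samples: Iterable[Sample]) -> np.ndarray:
    """All (length, diameter) measurement pairs across samples, (N, 2)."""
    arrays = [s.points() for s in samples]
    arrays = [a for a in arrays if len(a)]
    if not arrays:
        return np.empty((0, 2))
    return np.vstack(arrays)
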