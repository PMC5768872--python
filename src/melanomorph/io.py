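"""Readers and writers for measurement tables, feature tables and JSON reports.

Measurement tables are delimited text (comma or tab, auto-detected) with a
header row and one row per measured nanostructure; see
``measurements.TABLE_COLUMNS`` for the schema.  Reports are JSON and carry
provenance: a digest of the configuration, the seed, and the package version.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .measurements import Sample, samples_to_table, validate_and_filter


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.read(8192)
    if not head.strip():
        return ","
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in head.splitlines()[0] else ","


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited measurement table; empty file yields an empty frame."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"sample_id": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    return df


def read_samples(path: str | Path, min_measurements: int = 5):
    """Read + validate a measurement table; returns a ValidationResult."""
    df = read_measurement_table(path)
    if df.empty:
        return validate_and_filter(
            pd.DataFrame(columns=["sample_id", "length_nm", "diameter_nm"]),
            min_measurements=min_measurements,
        )
    return validate_and_filter(df, min_measurements=min_measurements)


def write_measurements(samples: Iterable[Sample], path: str | Path, sep: str = ",") -> None:
    samples_to_table(samples).to_csv(path, sep=sep, index=False)


def write_features(features: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    features.to_csv(path, sep=sep)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonify(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_report(payload: dict, path: str | Path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """JSON report with provenance header (config digest, seed, version)."""
    doc = {
        "provenance": {
            "package": "melanomorph",
            "version": __version__,
            "seed": seed,
            "config_digest": config_digest(config) if config is not None else None,
        },
        **_jsonify(payload),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
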