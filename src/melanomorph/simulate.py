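"""Synthetic measurement data with the statistical structure the analysis assumes.

Each colour class is modelled as a bivariate lognormal over (length, diameter):
melanosome axes are positive and right-skewed, and the lognormal gives closed
forms for the mean, CV and skew of the marginals, which the test suite uses as
oracles.  A fossil slab is simulated as a set of sampling locations whose
location-level mean morphology follows a spatially correlated Gaussian field
(squared-exponential kernel on the slab coordinates, applied on the log scale
so positivity is preserved), with designated platelet-bearing locations drawing
from the platelet class instead.

The default class parameters shipped here are illustrative morphologies in the
right size range for avian melanosomes; no result depends on them matching any
particular real species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .measurements import NanostructureMeasurement, Sample

_MAX_REJECTION = 0.99  # abort if >99% of bivariate draws violate length >= diameter


@dataclass(frozen=True)
class ClassMorphologyModel:
    """Bivariate lognormal morphology of one colour class.

    Parameters are on the log scale (log-nm); ``log_length_diameter_corr`` is
    the correlation of log length and log diameter.
    """

    colour_label: str
    log_length_mean: float
    log_length_sd: float
    log_diameter_mean: float
    log_diameter_sd: float
    log_length_diameter_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.log_length_sd <= 0 or self.log_diameter_sd <= 0:
            raise ValueError("log-scale standard deviations must be positive")
        if not -1.0 <= self.log_length_diameter_corr <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.log_length_mean < self.log_diameter_mean:
            raise ValueError(
                f"class {self.colour_label!r}: implied median aspect ratio < 1 "
                "(log length mean below log diameter mean)"
            )

    def shifted(self, dlog_length: float, dlog_diameter: float) -> "ClassMorphologyModel":
        """Model with log-means shifted (used for spatial fields and
        per-sample effects); skips the median-aspect-ratio check since local
        shifts may transiently violate it — rejection sampling still enforces
        length >= diameter per measurement."""
        obj = object.__new__(ClassMorphologyModel)
        object.__setattr__(obj, "colour_label", self.colour_label)
        object.__setattr__(obj, "log_length_mean", self.log_length_mean + dlog_length)
        object.__setattr__(obj, "log_length_sd", self.log_length_sd)
        object.__setattr__(obj, "log_diameter_mean", self.log_diameter_mean + dlog_diameter)
        object.__setattr__(obj, "log_diameter_sd", self.log_diameter_sd)
        object.__setattr__(obj, "log_length_diameter_corr", self.log_length_diameter_corr)
        return obj

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n (length, diameter) pairs; pairs violating length >= diameter
        are redrawn.  Raises if the rejection rate exceeds 99%."""
        mean = np.array([self.log_length_mean, self.log_diameter_mean])
        r = self.log_length_diameter_corr
        cov = np.array([
            [self.log_length_sd**2, r * self.log_length_sd * self.log_diameter_sd],
            [r * self.log_length_sd * self.log_diameter_sd, self.log_diameter_sd**2],
        ])
        chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
        out = np.empty((n, 2))
        filled = 0
        drawn = 0
        while filled < n:
            batch = max(n - filled, 64)
            z = rng.standard_normal((batch, 2))
            pairs = np.exp(mean + z @ chol.T)
            drawn += batch
            ok = pairs[:, 0] >= pairs[:, 1]
            keep = pairs[ok][: n - filled]
            out[filled : filled + len(keep)] = keep
            filled += len(keep)
            if drawn >= 2000 and filled / drawn < 1 - _MAX_REJECTION:
                raise ValueError(
                    f"class {self.colour_label!r}: rejection rate exceeds "
                    f"{_MAX_REJECTION:.0%}; degenerate class specification"
                )
        return out


def default_class_models() -> dict[str, ClassMorphologyModel]:
    """Illustrative class library spanning the avian melanosome morphospace.

    Rod-like black and grey melanosomes are long and narrow (grey with
    characteristically low variation), brown ones shorter and rounder,
    rod-iridescent ones the narrowest, platelet classes large and wide in the
    image plane, and the penguin brown-black class large and nearly spherical.
    """
    mk = ClassMorphologyModel
    models = [
        mk("black", np.log(1100.0), 0.20, np.log(280.0), 0.18, 0.30),
        mk("brown", np.log(650.0), 0.22, np.log(330.0), 0.20, 0.30),
        mk("grey", np.log(950.0), 0.10, np.log(230.0), 0.09, 0.30),
        mk("iridescent", np.log(1050.0), 0.16, np.log(175.0), 0.14, 0.25),
        mk("platelet_iridescence", np.log(1650.0), 0.16, np.log(480.0), 0.16, 0.30),
        mk("hummingbird_platelet", np.log(1150.0), 0.13, np.log(560.0), 0.14, 0.30),
        mk("penguin_brown_black", np.log(820.0), 0.15, np.log(640.0), 0.14, 0.50),
    ]
    return {m.colour_label: m for m in models}


PLATELET_CLASSES = ("platelet_iridescence", "hummingbird_platelet")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_library(
    models: Sequence[ClassMorphologyModel],
    n_samples_per_class: int = 20,
    n_meas_per_sample: int = 30,
    seed: int = 0,
    sample_effect_sd: float = 0.05,
) -> list[Sample]:
    """Simulate an extant training library.

    Each sample (one species patch) gets a small lognormal random effect on
    both log-means (``sample_effect_sd``), emulating between-species variation
    within a colour class, then draws its measurements from the class model.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 classes")
    if n_samples_per_class < 1 or n_meas_per_sample < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    samples: list[Sample] = []
    for model in models:
        for i in range(n_samples_per_class):
            eff = rng.normal(0.0, sample_effect_sd, size=2) if sample_effect_sd > 0 else np.zeros(2)
            local = model.shifted(eff[0], eff[1])
            pairs = local.draw(n_meas_per_sample, rng)
            samples.append(Sample(
                sample_id=f"{model.colour_label}_{i:03d}",
                source="extant",
                taxon=f"{model.colour_label}_taxon_{i:03d}",
                body_region="plumage",
                colour_label=model.colour_label,
                stacking_evidence=model.colour_label in PLATELET_CLASSES,
                measurements=[NanostructureMeasurement(l, d) for l, d in pairs],
            ))
    return samples


@dataclass
class SlabConfig:
    """Configuration of a simulated fossil slab.

    Defaults emulate the study system: ~53 sampling locations on a slab, 21
    of them platelet-bearing and spatially contiguous, roughly 40 measured
    nanostructures per location, and location-level morphology correlated
    over tens of millimetres.
    """

    n_locations: int = 53
    extent_mm: tuple[float, float] = (200.0, 100.0)
    correlation_length_mm: float = 40.0
    field_sd: float = 0.10           # SD of the spatial log-scale field (calibrated; see docs)
    n_platelet: int = 21
    platelet_locations: Optional[Sequence[int]] = None
    base_class: str = "black"
    platelet_class: str = "platelet_iridescence"
    n_meas_per_location: int = 40
    stacking_false_positive_rate: float = 0.0
    stacking_false_negative_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("n_locations must be >= 2")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation length must be positive")
        if not 0 <= self.n_platelet <= self.n_locations:
            raise ValueError("n_platelet out of range")


def _gp_field(coords: np.ndarray, ell: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """One draw of a zero-mean GP with squared-exponential kernel."""
    n = len(coords)
    if sd == 0:
        return np.zeros(n)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    K = sd**2 * np.exp(-d2 / (2.0 * ell**2))
    jitter = 1e-10 * sd**2
    for _ in range(8):
        try:
            chol = np.linalg.cholesky(K + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter *= 100.0
    else:
        raise ValueError("spatial covariance not positive definite after jitter")
    return chol @ rng.standard_normal(n)


def simulate_slab(
    config: SlabConfig,
    models: Optional[dict[str, ClassMorphologyModel]] = None,
) -> list[Sample]:
    """Simulate a fossil slab: spatially autocorrelated morphology plus
    designated platelet-bearing locations.

    Stacking evidence (the image criterion for platelet identification) is
    true exactly at platelet-designated locations, flipped at the configured
    false-positive / false-negative rates.
    """
    models = models or default_class_models()
    base = models[config.base_class]
    platelet = models[config.platelet_class]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))

    ext = np.asarray(config.extent_mm, dtype=float)
    coords = rng.uniform(0.0, 1.0, size=(config.n_locations, 2)) * ext

    if config.platelet_locations is not None:
        platelet_idx = set(int(i) for i in config.platelet_locations)
    elif config.n_platelet > 0:
        # contiguous platelet region: the n_platelet locations nearest a random anchor
        anchor = rng.uniform(0.0, 1.0, size=2) * ext
        order = np.argsort(((coords - anchor) ** 2).sum(1))
        platelet_idx = set(order[: config.n_platelet].tolist())
    else:
        platelet_idx = set()

    field_len = _gp_field(coords, config.correlation_length_mm, config.field_sd, rng)
    field_dia = _gp_field(coords, config.correlation_length_mm, config.field_sd, rng)

    samples: list[Sample] = []
    for i in range(config.n_locations):
        is_platelet = i in platelet_idx
        model = platelet if is_platelet else base
        local = model.shifted(field_len[i], field_dia[i])
        pairs = local.draw(config.n_meas_per_location, rng)
        evidence = is_platelet
        if is_platelet and config.stacking_false_negative_rate > 0:
            evidence = rng.random() >= config.stacking_false_negative_rate
        elif not is_platelet and config.stacking_false_positive_rate > 0:
            evidence = rng.random() < config.stacking_false_positive_rate
        samples.append(Sample(
            sample_id=f"slab_{i:03d}",
            source="fossil",
            taxon="fossil_taxon",
            body_region=f"region_{i:03d}",
            slab_xy=(float(coords[i, 0]), float(coords[i, 1])),
            colour_label="unknown",
            stacking_evidence=bool(evidence),
            measurements=[NanostructureMeasurement(l, d) for l, d in pairs],
        ))
    return samples


def true_platelet_ids(samples: Sequence[Sample], config: SlabConfig) -> set[str]:
    """Ground-truth platelet sample ids for a slab simulated with
    zero stacking noise (evidence flag equals truth)."""
    if config.stacking_false_negative_rate or config.stacking_false_positive_rate:
        raise ValueError("truth not recoverable from flags when stacking noise is nonzero")
    return {s.sample_id for s in samples if s.stacking_evidence}


def lognormal_mean(mu: float, sigma: float) -> float:
    """E[X] for log X ~ N(mu, sigma^2)."""
    return float(np.exp(mu + sigma**2 / 2.0))


def lognormal_cv(sigma: float) -> float:
    """CV of a lognormal: sqrt(exp(sigma^2) - 1)."""
    return float(np.sqrt(np.expm1(sigma**2)))


def lognormal_skew(sigma: float) -> float:
    """Skewness of a lognormal: (exp(sigma^2)+2) * sqrt(exp(sigma^2)-1)."""
    w = np.exp(sigma**2)
    return float((w + 2.0) * np.sqrt(w - 1.0))
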