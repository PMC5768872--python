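import numpy as np
import pytest

from melanomorph.measurements import pooled_points
from melanomorph.platelet import build_reference
from melanomorph.simulate import (PLATELET_CLASSES, SlabConfig,
                                  default_class_models, simulate_library,
                                  simulate_slab)


@pytest.fixture(scope="session")
def models():
    return default_class_models()


@pytest.fixture(scope="session")
def library(models):
    """Full 7-class extant training library (fixed seed)."""
    return simulate_library(list(models.values()), n_samples_per_class=15,
                            n_meas_per_sample=30, seed=101)


@pytest.fixture(scope="session")
def five_class_models(models):
    """Four base colour classes plus the platelet class."""
    keys = ("black", "brown", "grey", "iridescent", "platelet_iridescence")
    return [models[k] for k in keys]


@pytest.fixture(scope="session")
def reference(library):
    """Non-platelet extant reference morphospace at the default HDR level."""
    pts = pooled_points([s for s in library if s.colour_label not in PLATELET_CLASSES])
    return build_reference(pts, hdr_level=0.95)


@pytest.fixture(scope="session")
def slab(models):
    return simulate_slab(SlabConfig(seed=202), models)
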