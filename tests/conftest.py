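import numpy as np
import pandas as pd
import pytest

from nmrfield import (CohortDesign, EffectTable, MetaboliteSignature, PpmGrid,
                      SpectrumSet)


@pytest.fixture(scope="session")
def grid_2048():
    return PpmGrid.default(2048)


@pytest.fixture(scope="session")
def grid_1024():
    return PpmGrid.default(1024)


@pytest.fixture
def two_singlet_signatures():
    """Two well-separated singlets, handy for exact-recovery checks."""
    return [
        MetaboliteSignature("alpha", ((3.0, 1.0, 1.5),), 0.0),
        MetaboliteSignature("beta", ((7.0, 1.0, 1.5),), 0.0),
    ]


def make_set(intensities, ppm, class_ids=None, subject_ids=None):
    """SpectrumSet from a raw matrix with minimal metadata."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    class_ids = class_ids if class_ids is not None else [1] * n
    subject_ids = subject_ids if subject_ids is not None \
        else [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": [f"sample{i}" for i in range(n)],
        "subject_id": subject_ids,
        "class_id": class_ids,
        "chemo_flag": [0] * n,
    })
    return SpectrumSet(intensities, np.asarray(ppm, dtype=float), meta)


@pytest.fixture
def make_spectrum_set():
    return make_set


@pytest.fixture
def null_two_class_design():
    """Factory: an effect-free two-class design (class labels carry no signal)."""
    def _make(seed, n_per_class=20):
        return (CohortDesign(class_sizes={1: n_per_class, 6: n_per_class},
                             seed=seed),
                EffectTable({}))
    return _make
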