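import numpy as np
import pytest

from acpkit.ensemble_model import EnsembleConfig
from acpkit.sampling import LabeledMatrix
from acpkit.synthetic_data import BlobSpec, make_blobs


# small tree counts keep ensemble-based tests fast without changing behaviour
FAST_PARAMS = {
    "random_forest": {"n_estimators": 50},
    "gradient_boosting": {"n_estimators": 50},
    "hist_gradient_boosting": {"max_iter": 50},
}


@pytest.fixture
def fast_config():
    return EnsembleConfig(seed=0, member_params=FAST_PARAMS)


@pytest.fixture
def separable_blobs() -> LabeledMatrix:
    """Well-separated two-class blobs: any sensible classifier is perfect."""
    return make_blobs(
        BlobSpec(n_minority=60, n_majority=90, dim=4, class_separation=12.0,
                 within_class_spread=1.0, seed=11)
    )


@pytest.fixture
def overlapping_blobs() -> LabeledMatrix:
    """Imbalanced, overlapping blobs: the resampling regime of interest."""
    return make_blobs(
        BlobSpec(n_minority=40, n_majority=120, dim=6, class_separation=2.0,
                 within_class_spread=1.0, seed=5)
    )
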