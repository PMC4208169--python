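import numpy as np
import pytest

from harf.anb import train_class
from harf.features import FeatureVector
from harf.hierarchy import TYPE1_LABELS
from harf.simulator import default_registry as _default_registry


@pytest.fixture
def registry():
    return _default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_fv(values, names=None):
    values = np.asarray(values, dtype=float)
    if names is None:
        names = tuple(f"f{i}" for i in range(values.size))
    return FeatureVector(values=values, names=tuple(names))


#: per-motion scalar feature center used by the toy routing models
MOTION_CENTER = {"Walking": 2.0, "Sitting": 0.0, "Standing": 1.0, "Jogging": 3.0}


@pytest.fixture
def type1_models():
    """One-feature models for all ten Type-1 labels, well separated."""
    models = []
    for lab in TYPE1_LABELS:
        motion = lab.name.split("/")[1]
        center = MOTION_CENTER[motion]
        models.append(
            train_class(
                [make_fv([center + d]) for d in (-0.1, 0.0, 0.1)],
                chunk_size=10,
                prior=1.0 / len(TYPE1_LABELS),
                label=lab.name,
            )
        )
    return models
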