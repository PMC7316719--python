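import numpy as np
import pytest

from ssbondnet import (DisulfideBondClassifier, make_feature_clouds,
                       make_structure)


@pytest.fixture(scope="session")
def cloud_dataset():
    """Moderate geometric benchmark shared across model/predictor tests."""
    return make_feature_clouds(1000, seed=42)


@pytest.fixture(scope="session")
def trained_classifier(cloud_dataset):
    clf = DisulfideBondClassifier(random_state=7)
    clf.fit(cloud_dataset.X_train, cloud_dataset.y_train)
    return clf


@pytest.fixture()
def line_fixture():
    """20-residue structure with 2 planted bonds and 1 non-bonded decoy."""
    model, truth = make_structure(20, 2, seed=3, decoys=1)
    return model, truth


def rigid_motion(rng):
    """Random rotation matrix + translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=20.0, size=3)
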