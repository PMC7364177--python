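import numpy as np
import pytest

import mvpkit
from mvpkit import synthetic


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable classification volumes: effect 5 SD in a 3^3 cube."""
    spec = mvpkit.FixtureSpec(seed=11, effect=5.0, n_per_class=20, n_folds=10)
    vols, labels, folds, space = mvpkit.classification_dataset(spec)
    fm = synthetic.as_feature_matrix(vols, space)
    return fm, labels, folds, spec


@pytest.fixture(scope="session")
def null_dataset():
    """No class signal at all (effect = 0)."""
    spec = mvpkit.FixtureSpec(seed=13, effect=0.0, n_per_class=20, n_folds=10)
    vols, labels, folds, space = mvpkit.classification_dataset(spec)
    fm = synthetic.as_feature_matrix(vols, space)
    return fm, labels, folds, spec


@pytest.fixture(scope="session")
def volume_files(tmp_path_factory):
    """A small on-disk NIfTI fixture set (volumes, mask, labels, folds)."""
    out = tmp_path_factory.mktemp("volset")
    spec = mvpkit.FixtureSpec(seed=17, grid=(6, 6, 6), n_per_class=6,
                              n_folds=3, signal_region=((1, 4), (1, 4), (1, 4)))
    paths = mvpkit.make_classification_volumes(spec, out)
    return paths, spec


@pytest.fixture
def svc_pipeline():
    return mvpkit.Pipeline(model=mvpkit.make_model("svm", "classify"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
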