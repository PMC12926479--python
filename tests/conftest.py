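import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """A small easy synthetic dataset (64 train / 13 val / 3 test at 128 px)."""
    from dfsnet.data import easy_spec, make_dataset

    root = tmp_path_factory.mktemp("data") / "easy"
    make_dataset(80, easy_spec(128), seed=11, out_dir=root)
    return root


@pytest.fixture(scope="session")
def smoke_history(easy_dataset, tmp_path_factory):
    """One reduced-scale training run shared by the smoke-learning checks.

    Tiny DFSNet on the 64 easy training scenes at 128², using the
    package's smoke-benchmark recipe; validation mAP every 10 epochs.
    """
    from dfsnet.train import smoke_train_config, train

    out = tmp_path_factory.mktemp("runs") / "smoke"
    return train(smoke_train_config(easy_dataset, out, seed=7, epochs=80))
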