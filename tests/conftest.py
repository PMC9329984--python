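import numpy as np
import pytest

from smearopt.data import bundle_to_arrays, resize_images, split_dataset
from smearopt.synthetic import SmearParams, generate_dataset


@pytest.fixture(scope="session")
def desk_data():
    """Standardized 32x32 synthetic smear arrays: 200 train / 40 val / 40 test."""
    params = SmearParams().for_size(96)
    bundle = generate_dataset(140, 140, params=params, seed=7)
    bundle = resize_images(bundle, 32, 32)
    bundle = split_dataset(bundle, fractions=(5 / 7, 1 / 7, 1 / 7), seed=0)
    Xtr, ytr = bundle_to_arrays(bundle, "train")
    Xval, yval = bundle_to_arrays(bundle, "val")
    Xtest, ytest = bundle_to_arrays(bundle, "test")
    mean = Xtr.mean(axis=(0, 2, 3), keepdims=True)
    sd = Xtr.std(axis=(0, 2, 3), keepdims=True)
    return {
        "train": ((Xtr - mean) / sd, ytr),
        "val": ((Xval - mean) / sd, yval),
        "test": ((Xtest - mean) / sd, ytest),
    }


@pytest.fixture(scope="session")
def separable_images():
    """Trivially separable 16x16 image set: dark class 0, bright class 1."""
    rng = np.random.default_rng(42)
    n = 60
    X0 = rng.normal(-1.0, 0.3, size=(n, 3, 16, 16))
    X1 = rng.normal(1.0, 0.3, size=(n, 3, 16, 16))
    X = np.concatenate([X0, X1]).astype(np.float32)
    y = np.array([0] * n + [1] * n)
    order = rng.permutation(2 * n)
    X, y = X[order], y[order]
    return (X[:80], y[:80]), (X[80:], y[80:])
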