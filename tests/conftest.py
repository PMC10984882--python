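import numpy as np
import pytest

from eauscan.phantom import LesionSpec, PhantomSpec, generate_dataset, generate_phantom

# compact frame geometry used throughout the suite; scaled down from the
# clinical 797x657 resolution but with every visual feature present
SMALL_GEOM = dict(width=128, height=112, metadata_margin=10, field_radius=40.0, circle_radius=10.0)

# 64x64 frames for classifier training runs
TRAIN_GEOM = dict(width=64, height=64, metadata_margin=5, field_radius=23.0, circle_radius=6.0)


@pytest.fixture
def normal_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL_GEOM, marks=0, lesion=None, seed=7)


@pytest.fixture
def lesion_phantom_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL_GEOM, marks=3, lesion=LesionSpec(), seed=7)


@pytest.fixture
def phantom_pair(normal_spec, lesion_phantom_spec):
    """Same seed with and without a lesion; identical speckle realization."""
    with_lesion = generate_phantom(lesion_phantom_spec)
    without = generate_phantom(normal_spec)
    return with_lesion, without


@pytest.fixture(scope="session")
def train_dataset():
    """200 labeled 64x64 phantoms (100 normal / 100 abnormal), 40 patients."""
    spec = PhantomSpec(**TRAIN_GEOM, marks=0, lesion=LesionSpec(), seed=0)
    ds = generate_dataset(100, 100, 40, spec, seed=0)
    X = [r.pixels[:, :, 0] for r in ds.records]
    y = np.array([1 if r.label == "abnormal" else 0 for r in ds.records])
    return X, y, ds


def degenerate_val_setup(n_train: int = 12, n_val: int = 8, size: int = 16):
    """Training data whose validation accuracy is constant by construction:
    all validation images are identical, labels split half/half, so any
    deterministic model scores exactly 0.5 every epoch."""
    rng = np.random.default_rng(0)
    X_train = [rng.uniform(0, 255, (size, size)) for _ in range(n_train)]
    y_train = np.arange(n_train) % 2
    X_val = [np.full((size, size), 128.0) for _ in range(n_val)]
    y_val = np.arange(n_val) % 2
    return X_train, y_train, X_val, y_val
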