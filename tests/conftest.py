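import numpy as np
import pytest

from mritumor import GrayImage, PhantomSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def meningioma_phantom():
    """One low-noise phantom with ground truth, shared across tests."""
    return generate(PhantomSpec(tumor_class="meningioma", noise_sigma=0.02, seed=11))


@pytest.fixture(scope="session")
def phantom_feature_table():
    """A small class-balanced feature table from the real pipeline path.

    Built once per session (segmentation dominates the cost) and reused
    by the selection and classification tests.
    """
    from mritumor import PipelineConfig
    from mritumor.phantom import generate_dataset
    from mritumor.pipeline import build_feature_table, derive_seed

    cfg = PipelineConfig(seed=5)
    samples, _ = generate_dataset(
        10, seed=derive_seed(5, "simulate"), base_spec=PhantomSpec()
    )
    return build_feature_table(
        [s.image for s in samples], [s.class_label for s in samples], cfg
    )


def as_gray(arr, hi=1.0):
    arr = np.asarray(arr, dtype=float)
    return GrayImage(arr, value_range=(min(0.0, float(arr.min())), hi))
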