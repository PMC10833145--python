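import numpy as np
import pytest

import morphosample as ms


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_shape(rng, k=14):
    """A non-degenerate random configuration."""
    return rng.standard_normal((k, 2))


@pytest.fixture
def small_dataset():
    """A small study-structured dataset with sliders and classifiers (n=20)."""
    spec = ms.GeneratorSpec(
        groups=[
            ms.GroupSpec("sp", "F", 10, cs_log10_mean=1.52),
            ms.GroupSpec("sp", "M", 10, cs_log10_mean=1.48),
        ],
        view="lateral_cranium",
        seed=5,
    )
    ds, truth = ms.generate_dataset(spec)
    return ds, truth


@pytest.fixture
def polygon_dataset():
    """No-semilandmark dataset on a 10-point template (n=24)."""
    spec = ms.GeneratorSpec(
        groups=[ms.GroupSpec("sp", "F", 12), ms.GroupSpec("sp", "M", 12)],
        template=ms.polygon_template(10),
        seed=11,
    )
    ds, truth = ms.generate_dataset(spec)
    return ds, truth
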