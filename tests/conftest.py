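import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


@pytest.fixture(scope="session")
def clean_batch20():
    """20 clean 128 px fixtures with full ground truth (shared, read-only)."""
    from phenoseg.synthetic import make_fixture_batch

    return make_fixture_batch(20, seed=101, size=128)


@pytest.fixture(scope="session")
def small_batch3():
    """3 small fixtures for fast pipeline tests."""
    from phenoseg.synthetic import make_fixture_batch

    return make_fixture_batch(3, seed=7, size=96)
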