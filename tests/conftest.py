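import numpy as np
import pytest

import omixblup as ob


@pytest.fixture(scope="session")
def study_bundle():
    """Partially transcribed study miniature used across modules."""
    return ob.make_study_bundle(n_total=150, n_transcribed=40, m=400, g=120,
                                seed=42)


@pytest.fixture(scope="session")
def transcribed_bundle():
    """Fully transcribed population with a strongly expression-mediated trait."""
    return ob.make_study_bundle(n_total=120, n_transcribed=120, m=400, g=120,
                                h2=0.6, mediation_share=0.9, expr_h2=0.9,
                                seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def random_psd(rng, n, jitter=0.05):
    """Random symmetric PSD matrix with a safely invertible diagonal."""
    A = rng.normal(size=(n, max(n, 2 * n)))
    K = A @ A.T / A.shape[1]
    return K + jitter * np.eye(n)
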