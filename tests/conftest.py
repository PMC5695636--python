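import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_tsv(tmp_path):
    """3 samples x 2 features TSV matrix."""
    p = tmp_path / "m.tsv"
    p.write_text("sample\tgA\tgB\nS1\t1.0\t10\nS2\t2.0\t20\nS3\t3.0\t30\n")
    return p


def make_triangle(n=300, noise=0.01, seed=0, d=2):
    """Samples from a planted 2-simplex in d dims, with Gaussian noise."""
    rng = np.random.default_rng(seed)
    V = np.zeros((3, d))
    V[0, 0], V[1, 0], V[1, 1], V[2, 1] = 0.0, 1.0, 0.0, 1.0
    V[2, 0] = 0.5
    F = rng.dirichlet(np.ones(3), n)
    X = F @ V + rng.normal(0, noise, (n, d))
    return X, F, V
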