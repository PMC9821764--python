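import numpy as np
import pytest

from rcfgl import CovariancePanel, ExpressionPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel(rng):
    """K=2 panel: 8 samples x 4 genes per condition."""
    Y = [rng.normal(0, 1, (8, 4)) for _ in range(2)]
    return ExpressionPanel(conditions=["A", "B"], Y=Y,
                           gene_ids=["g1", "g2", "g3", "g4"])


def random_covariance_panel(rng, K, p, n):
    """Covariance panel from random Gaussian data (PD for n > p)."""
    S = []
    for _ in range(K):
        X = rng.normal(0, 1, (n, p))
        Xc = X - X.mean(axis=0)
        S.append(Xc.T @ Xc / n)
    return CovariancePanel(conditions=[f"c{k}" for k in range(K)],
                           S=np.array(S), n=np.full(K, n),
                           gene_ids=[f"g{i}" for i in range(p)])


def random_binary_weights(rng, K, p):
    W = []
    for _ in range(K - 1):
        w = np.triu(rng.integers(0, 2, (p, p)).astype(float), 1)
        W.append(w + w.T + np.eye(p))
    return W
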