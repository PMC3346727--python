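import numpy as np
import pytest

from trfpathway import GenotypeMatrix


def make_matrix(G: np.ndarray, y: np.ndarray, prefix: str = "snp") -> GenotypeMatrix:
    n, p = G.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"{prefix}{j}" for j in range(p)],
        dosages=np.asarray(G, dtype=np.int8),
        phenotype=np.asarray(y, dtype=np.int8),
    )


@pytest.fixture
def noise_matrix():
    """Factory: balanced case-control matrix with phenotype-independent SNPs."""

    def _make(n: int = 200, p: int = 50, seed: int = 0, maf: float = 0.3):
        rng = np.random.default_rng(seed)
        G = rng.binomial(2, maf, size=(n, p)).astype(np.int8)
        y = np.zeros(n, dtype=np.int8)
        y[: n // 2] = 1
        return make_matrix(G, y)

    return _make


@pytest.fixture
def separator_matrix():
    """Factory: column 0 perfectly separates cases (dosage 2) from controls."""

    def _make(n: int = 200, p_noise: int = 19, seed: int = 5):
        rng = np.random.default_rng(seed)
        G = rng.binomial(2, 0.3, size=(n, p_noise + 1)).astype(np.int8)
        y = np.zeros(n, dtype=np.int8)
        y[: n // 2] = 1
        G[:, 0] = np.where(y == 1, 2, 0)
        return make_matrix(G, y)

    return _make
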