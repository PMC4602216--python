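import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20150913)


def sample_ztp(lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n zero-truncated Poisson(lam) variates by rejecting zeros."""
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.poisson(lam, size=max(2 * n, 100))
        out = np.concatenate([out, draw[draw >= 1]])
    return out[:n]


def sample_zt_mixture(
    weights, rates, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-truncated mixed-Poisson sample: mix first, then condition on >=1."""
    weights = np.asarray(weights, dtype=float)
    rates = np.asarray(rates, dtype=float)
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        comp = rng.choice(len(weights), size=2 * n, p=weights)
        draw = rng.poisson(rates[comp])
        out = np.concatenate([out, draw[draw >= 1]])
    return out[:n]


def histogram(values) -> dict[int, int]:
    ks, cs = np.unique(np.asarray(values, dtype=np.int64), return_counts=True)
    return dict(zip(ks.tolist(), cs.tolist()))
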