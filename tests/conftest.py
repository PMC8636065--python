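import numpy as np
import pandas as pd
import pytest

from bxdtwas.io import ExpressionMatrix, Scale
from bxdtwas.simulate import SimulationConfig, simulate_panel


def matrix_with_exact_correlations(
    corr: np.ndarray, n_samples: int, rng: np.random.Generator, scale: float = 1.0
) -> np.ndarray:
    """Rows whose *sample* Pearson correlation matrix equals ``corr`` exactly.

    Builds mean-zero orthonormal basis vectors of length ``n_samples`` and
    mixes them through the Cholesky factor of ``corr``, so the empirical
    correlations match the targets to machine precision (needs
    n_samples >= k + 1 for k rows).
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    assert n_samples >= k + 1, "need n_samples > number of rows"
    raw = rng.standard_normal((n_samples, k))
    raw -= raw.mean(axis=0)  # orthogonal to the all-ones vector
    q, _ = np.linalg.qr(raw)
    L = np.linalg.cholesky(corr)
    return scale * (L @ q.T)


def expression_from_values(
    values: np.ndarray, scale: Scale = Scale.MODIFIED_Z
) -> ExpressionMatrix:
    genes = [f"G{i + 1:04d}" for i in range(values.shape[0])]
    strains = [f"BXD{i + 1:03d}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=strains), scale)


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel, shared read-only across tests."""
    return simulate_panel(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)
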