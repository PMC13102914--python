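import warnings

import numpy as np
import pandas as pd
import pytest

from repgea.simulate import EnvSpec, SimConfig, simulate_replicate_pair


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A desk-sized two-landscape study for fast end-to-end tests."""
    return SimConfig(
        n_neutral_loci=300,
        n_adaptive_loci=12,
        n_individuals_per_site=(6, 5),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_replicate_pair(tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    """Full pipeline bundle on the tiny study (shared across tests)."""
    from repgea.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(sim=tiny_config, n_perm=99, seed=tiny_config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


def exact_correlation_table(corr: np.ndarray, names, n_rows: int, seed: int = 0) -> pd.DataFrame:
    """Data whose *sample* correlation matrix equals ``corr`` exactly.

    Random columns are orthonormalized in the centered space and mixed by a
    square root of ``corr``; requires n_rows > len(names) + 1.
    """
    p = len(names)
    assert n_rows > p + 1
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_rows, p))
    # centered orthonormal columns: QR of a centered matrix stays centered
    Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.clip(w, 0, None))
    X = Q @ root.T
    return pd.DataFrame(X, columns=list(names))
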