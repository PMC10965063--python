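import numpy as np
import pytest

from insider.factor_model import (
    CovariateBlock,
    ExpressionMatrix,
    FactorBlock,
    GeneLoadings,
    Hyperparams,
    ModelFit,
    observation_block,
)


def one_hot(levels, n_levels, name, kind="categorical"):
    levels = np.asarray(levels)
    design = np.zeros((levels.size, n_levels))
    design[np.arange(levels.size), levels] = 1.0
    return CovariateBlock(name=name, design=design, kind=kind)


def random_fit(seed=0, n=6, m=4, k=2, n_blocks=2, include_obs=False):
    """A small random model (not fitted to anything) for algebra tests."""
    rng = np.random.default_rng(seed)
    blocks = []
    for b in range(n_blocks):
        n_lev = rng.integers(2, 4)
        cov = one_hot(rng.integers(0, n_lev, size=n), n_lev, f"cov{b}")
        fac = FactorBlock(f"cov{b}", rng.standard_normal((n_lev, k)))
        blocks.append((cov, fac))
    if include_obs:
        cov = observation_block(n)
        blocks.append((cov, FactorBlock("observation",
                                        rng.standard_normal((n, k)))))
    loadings = GeneLoadings(rng.standard_normal((k, m)))
    hp = Hyperparams(K=k, ridge_lambda=0.5, alpha=0.3, seed=seed)
    return ModelFit(blocks=blocks, loadings=loadings, hyperparams=hp)


def random_data(seed=0, n=6, m=4, missing=0.2):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, m))
    mask = rng.random((n, m)) > missing
    # keep at least one observed entry per row/column
    for i in range(n):
        if not mask[i].any():
            mask[i, rng.integers(m)] = True
    for j in range(m):
        if not mask[:, j].any():
            mask[rng.integers(n), j] = True
    return ExpressionMatrix(np.where(mask, values, 0.0), mask)


@pytest.fixture
def small_fit():
    return random_fit(seed=1)


@pytest.fixture
def small_data():
    return random_data(seed=2)
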