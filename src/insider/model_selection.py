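"""Hyperparameter selection by held-out matrix entries.

The protocol: draw a fraction of the *observed* entries (10% by default)
without replacement as a test set, train on the rest, and score candidate
hyperparameters by RMSE of the reconstruction on the held-out entries.
Rank K is selected first on a grid with short (30-iteration) runs at
lambda = 0.1, alpha = 0 — every update is then closed-form — and the
{lambda, alpha} pair is selected afterwards at the chosen K.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .factor_model import CovariateBlock, ExpressionMatrix, Hyperparams, ModelFit
from .optimizer import fit, holdout_rmse

__all__ = [
    "split_holdout",
    "select_rank",
    "select_regularization",
    "fit_with_selection",
    "DEFAULT_K_GRID",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_K_GRID = tuple(range(10, 31, 2))
DEFAULT_LAMBDA_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

TUNE_ITERS = 30  # short runs are sufficient for consistent selection


def split_holdout(
    data: ExpressionMatrix, fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split observed entries into disjoint train and test masks.

    Exactly ``round(fraction * n_observed)`` entries go to the test mask;
    their union is the observed mask.  Warns (not fatal) if some row or
    column loses all its training entries.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("holdout fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    obs_idx = np.flatnonzero(data.mask)
    n_test = int(round(fraction * obs_idx.size))
    test_flat = rng.choice(obs_idx, size=n_test, replace=False)
    test_mask = np.zeros(data.mask.shape, dtype=bool)
    test_mask.flat[test_flat] = True
    train_mask = data.mask & ~test_mask
    if (~train_mask.any(axis=1)).any() or (~train_mask.any(axis=0)).any():
        warnings.warn(
            "holdout split left a row or column with no training entries; "
            "ridge regularization will keep the fit defined",
            stacklevel=2,
        )
    return train_mask, test_mask


def _tune_fit(data, design, train_mask, test_mask, hp) -> float:
    train = ExpressionMatrix(
        data.values, train_mask, data.sample_ids, data.gene_ids
    )
    model = fit(train, design, hp)
    return holdout_rmse(model, data, test_mask)


def select_rank(
    data: ExpressionMatrix,
    design: list[CovariateBlock],
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
    fraction: float = 0.1,
    tune_iters: int = TUNE_ITERS,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[int, pd.Series]:
    """Pick the rank K minimizing held-out RMSE (ties toward smaller K).

    Tuning runs use lambda = 0.1 (to avoid singular matrix inverses) and
    alpha = 0 so every update has a closed form.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    train_mask, test_mask = (
        split if split is not None else split_holdout(data, fraction, seed)
    )
    rmses = {}
    for K in k_grid:
        hp = Hyperparams(K=K, ridge_lambda=0.1, alpha=0.0,
                         max_iter=tune_iters, tol=1e-12, seed=seed)
        rmses[K] = _tune_fit(data, design, train_mask, test_mask, hp)
    table = pd.Series(rmses, name="holdout_rmse")
    # ties toward smaller K: stable argmin over the sorted grid
    best = min(sorted(rmses), key=lambda k: (rmses[k], k))
    return int(best), table


def select_regularization(
    data: ExpressionMatrix,
    design: list[CovariateBlock],
    K: int,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    seed: int = 0,
    fraction: float = 0.1,
    tune_iters: int = TUNE_ITERS,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Pick {lambda, alpha} minimizing held-out RMSE at fixed K.

    Ties are broken toward larger lambda then larger alpha (stronger
    regularization).
    """
    lambda_grid, alpha_grid = list(lambda_grid), list(alpha_grid)
    if not lambda_grid or not alpha_grid:
        raise ValueError("hyperparameter grids must be nonempty")
    train_mask, test_mask = (
        split if split is not None else split_holdout(data, fraction, seed)
    )
    rows = []
    for lam in lambda_grid:
        for alpha in alpha_grid:
            hp = Hyperparams(K=K, ridge_lambda=lam, alpha=alpha,
                             max_iter=tune_iters, tol=1e-12, seed=seed)
            rows.append((lam, alpha,
                         _tune_fit(data, design, train_mask, test_mask, hp)))
    table = pd.DataFrame(rows, columns=["lambda", "alpha", "holdout_rmse"])
    best = min(rows, key=lambda r: (r[2], -r[0], -r[1]))
    return float(best[0]), float(best[1]), table


def fit_with_selection(
    data: ExpressionMatrix,
    design: list[CovariateBlock],
    k_grid=DEFAULT_K_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    seed: int = 0,
    fraction: float = 0.1,
    tune_iters: int = TUNE_ITERS,
    refit_on_all: bool = True,
    final_hp: Hyperparams | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ModelFit, dict]:
    """Full selection protocol: rank grid, then {lambda, alpha} grid, then a
    final fit at the chosen hyperparameters (on all observed data by default).
    """
    if split is None:
        split = split_holdout(data, fraction, seed)
    K, k_table = select_rank(
        data, design, k_grid, seed, fraction, tune_iters, split=split
    )
    lam, alpha, la_table = select_regularization(
        data, design, K, lambda_grid, alpha_grid, seed, fraction,
        tune_iters, split=split,
    )
    base = final_hp if final_hp is not None else Hyperparams()
    hp = replace(base, K=K, ridge_lambda=lam, enet_lambda=None, alpha=alpha,
                 seed=seed)
    hp.enet_lambda = hp.ridge_lambda
    if refit_on_all:
        model = fit(data, design, hp)
    else:
        train_mask, _ = split
        train = ExpressionMatrix(
            data.values, train_mask, data.sample_ids, data.gene_ids
        )
        model = fit(train, design, hp)
    info = {
        "K": K, "lambda": lam, "alpha": alpha,
        "rank_table": k_table, "reg_table": la_table, "split": split,
    }
    return model, info
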