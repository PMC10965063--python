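"""Synthetic data generators and scoring for the validation studies.

Four generative designs are provided:

* ``simulate_insider_design`` — the model's own generative process: two
  balanced categorical covariates plus a per-sample interaction, all sharing
  a rank-5 gene loading matrix, with 30% of genes silenced (their loading
  columns zeroed, so their true signal is exactly zero).
* ``simulate_sda_design`` — a trilinear (tensor) model T_nlg = sum_c E_nc
  F_lc V_cg over a 50 x 5 x 200 tensor, flattened sample-major to 250 x 200
  with the two categorical design matrices attached.
* ``simulate_linear_design`` — an additive two-way ANOVA per gene with NO
  low-rank structure across genes (coefficients drawn independently per
  gene): the misspecification stress test.
* ``simulate_missing_design`` — a 400 x 1000 donor/phenotype/tissue study
  (50 donors x 8 tissues, 27 healthy / 23 diseased) with a phenotype x
  tissue interaction and configurable missingness: whole sample rows absent
  per a structured donor-tissue availability pattern (or at random), plus
  missing entries at random.

In every design the additive noise is drawn as N(0, delta^2), i.e. ``delta``
parameterizes the noise *standard deviation*.

All generators return the noiseless signal alongside the data so recovery
error can be scored exactly, including on masked rows and entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .factor_model import (
    CovariateBlock,
    ExpressionMatrix,
    Hyperparams,
    observation_block,
    reconstruct,
)
from .model_selection import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_LAMBDA_GRID,
    fit_with_selection,
    split_holdout,
)
from .optimizer import fit

__all__ = [
    "SimulatedDataset",
    "simulate_insider_design",
    "simulate_sda_design",
    "simulate_linear_design",
    "simulate_missing_design",
    "rmse",
    "baseline_rmse",
    "fit_ridge_baseline",
    "run_table",
]


@dataclass
class SimulatedDataset:
    """A generated dataset: observed data, noiseless truth, and provenance."""

    Z: ExpressionMatrix
    truth: np.ndarray
    design: list[CovariateBlock]
    truth_blocks: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    missing_rows: np.ndarray | None = None  # rows absent entirely, if any
    entry_mask: np.ndarray | None = None  # entry-level missing among kept rows


def _one_hot(levels: np.ndarray, n_levels: int, name: str,
             kind: str = "categorical",
             level_ids=None) -> CovariateBlock:
    design = np.zeros((levels.size, n_levels))
    design[np.arange(levels.size), levels] = 1.0
    return CovariateBlock(name=name, design=design, kind=kind,
                          level_ids=level_ids)


def simulate_insider_design(delta: float = 0.25, seed: int = 0,
                            n_genes: int = 200,
                            silenced_fraction: float = 0.3) -> SimulatedDataset:
    """Data generated exactly from the additive factor model.

    250 samples x ``n_genes`` genes, rank 5.  Covariate E has 50 balanced
    levels (5 samples each), covariate F has 5 levels (cycling within each
    E level), and the interaction R is per-sample (identity design).  A
    ``silenced_fraction`` of gene loading columns is zeroed before adding
    N(0, delta^2) noise, so silenced genes carry no signal.
    """
    rng = np.random.default_rng(seed)
    K, n = 5, 250
    E = rng.standard_normal((50, K))
    F = rng.standard_normal((5, K))
    R = rng.standard_normal((n, K))
    V = rng.standard_normal((K, n_genes))
    silenced = rng.choice(n_genes, size=int(round(silenced_fraction * n_genes)),
                          replace=False)
    V[:, silenced] = 0.0
    lev_e = np.repeat(np.arange(50), 5)
    lev_f = np.arange(n) % 5
    truth = (E[lev_e] + F[lev_f] + R) @ V
    Z = truth + delta * rng.standard_normal(truth.shape)
    design = [_one_hot(lev_e, 50, "E"), _one_hot(lev_f, 5, "F")]
    return SimulatedDataset(
        Z=ExpressionMatrix.from_values(Z),
        truth=truth,
        design=design,
        truth_blocks={"E": E, "F": F, "R": R, "V": V, "silenced": silenced},
        noise_sd=delta,
        seed=seed,
    )


def simulate_sda_design(sigma: float = 0.25, seed: int = 0) -> SimulatedDataset:
    """Trilinear tensor data, flattened sample-major to a 250 x 200 matrix.

    T_nlg = sum_c E_nc F_lc V_cg with E 50 x 5, F 5 x 5, V 5 x 200 standard
    normal; the flattened row for (n, l) is (E_n * F_l) V where * is the
    elementwise product.  Ordering is n-major: row index = 5 n + l.
    """
    rng = np.random.default_rng(seed)
    K = 5
    E = rng.standard_normal((50, K))
    F = rng.standard_normal((5, K))
    V = rng.standard_normal((K, 200))
    tensor = np.einsum("nc,lc,cg->nlg", E, F, V)
    truth = tensor.reshape(250, 200)
    Z = truth + sigma * rng.standard_normal(truth.shape)
    lev_e = np.repeat(np.arange(50), 5)
    lev_f = np.tile(np.arange(5), 50)
    design = [_one_hot(lev_e, 50, "E"), _one_hot(lev_f, 5, "F")]
    return SimulatedDataset(
        Z=ExpressionMatrix.from_values(Z),
        truth=truth,
        design=design,
        truth_blocks={"E": E, "F": F, "V": V, "tensor": tensor},
        noise_sd=sigma,
        seed=seed,
    )


def simulate_linear_design(sigma: float = 0.25, seed: int = 0) -> SimulatedDataset:
    """Two-way additive linear model: T = X_E E + X_F F, no gene low-rank.

    100 samples x 200 genes; X_E has 20 balanced levels (5 samples each),
    X_F has 5 levels (cycling, 20 samples each); per-gene coefficients
    E (20 x 200) and F (5 x 200) are i.i.d. standard normal.
    """
    rng = np.random.default_rng(seed)
    n, m = 100, 200
    E = rng.standard_normal((20, m))
    F = rng.standard_normal((5, m))
    lev_e = np.repeat(np.arange(20), 5)
    lev_f = np.arange(n) % 5
    truth = E[lev_e] + F[lev_f]
    Z = truth + sigma * rng.standard_normal(truth.shape)
    design = [_one_hot(lev_e, 20, "E"), _one_hot(lev_f, 5, "F")]
    return SimulatedDataset(
        Z=ExpressionMatrix.from_values(Z),
        truth=truth,
        design=design,
        truth_blocks={"E": E, "F": F},
        noise_sd=sigma,
        seed=seed,
    )


def _structured_row_pattern(rng: np.random.Generator, n_donors: int = 50,
                            n_tissues: int = 8, min_tissues: int = 4,
                            target_available: int = 229) -> np.ndarray:
    """Donor x tissue availability: each donor keeps >= min_tissues of
    n_tissues tissues, with exactly ``target_available`` kept in total.

    Every donor starts at the minimum; the remaining slots are distributed
    uniformly at random over donors' free tissue slots.
    """
    base = n_donors * min_tissues
    extra = target_available - base
    if not 0 <= extra <= n_donors * (n_tissues - min_tissues):
        raise ValueError("target_available incompatible with tissue bounds")
    counts = np.full(n_donors, min_tissues)
    free = np.repeat(np.arange(n_donors), n_tissues - min_tissues)
    chosen = rng.choice(free.size, size=extra, replace=False)
    np.add.at(counts, free[chosen], 1)
    keep = np.zeros((n_donors, n_tissues), dtype=bool)
    for d in range(n_donors):
        keep[d, rng.choice(n_tissues, size=counts[d], replace=False)] = True
    return keep


def simulate_missing_design(delta: float = 0.25, pattern: str = "structured",
                            seed: int = 0, n_genes: int = 1000,
                            entry_missing: float = 0.05,
                            target_available: int = 229) -> SimulatedDataset:
    """Donor/phenotype/tissue design (400 x n_genes) with missing data.

    R = (X_D D + X_P P + X_T T + X_W W) V with D 50x5, P 2x5, T 8x5, W 16x5
    (phenotype-major interaction levels), V 5 x n_genes, all standard normal.
    Donors 0..26 are healthy, 27..49 diseased.  Patterns:

    * ``"structured"`` — whole rows removed by the donor-tissue availability
      pattern (each donor keeps at least 4 of 8 tissues; 229 rows kept by
      default), then ``entry_missing`` of the remaining entries masked.
    * ``"random"`` — the same number of rows removed at random (regenerated
      if any donor loses all rows), then entries masked.
    * ``"entries_only"`` — no rows removed; only entries masked.
    """
    if pattern not in ("structured", "random", "entries_only"):
        raise ValueError(f"unknown missing pattern '{pattern}'")
    rng = np.random.default_rng(seed)
    n_donors, n_tissues, K = 50, 8, 5
    n = n_donors * n_tissues
    D = rng.standard_normal((n_donors, K))
    P = rng.standard_normal((2, K))
    T = rng.standard_normal((n_tissues, K))
    W = rng.standard_normal((2 * n_tissues, K))
    V = rng.standard_normal((K, n_genes))
    donor = np.repeat(np.arange(n_donors), n_tissues)
    tissue = np.tile(np.arange(n_tissues), n_donors)
    pheno = (donor >= 27).astype(int)  # 27 healthy, 23 diseased
    inter = pheno * n_tissues + tissue  # phenotype-major levels
    truth = (D[donor] + P[pheno] + T[tissue] + W[inter]) @ V
    Z = truth + delta * rng.standard_normal(truth.shape)

    if pattern == "structured":
        keep2d = _structured_row_pattern(
            rng, n_donors, n_tissues, target_available=target_available
        )
        row_kept = keep2d.reshape(-1)
    elif pattern == "random":
        n_missing = int(np.floor((1.0 - target_available / n) * n))
        while True:
            drop = rng.choice(n, size=n_missing, replace=False)
            row_kept = np.ones(n, dtype=bool)
            row_kept[drop] = False
            if np.all(np.bincount(donor[row_kept], minlength=n_donors) > 0):
                break
    else:
        row_kept = np.ones(n, dtype=bool)

    mask = np.repeat(row_kept[:, None], n_genes, axis=1)
    entry_mask = np.ones((n, n_genes), dtype=bool)
    if entry_missing > 0:
        avail = np.flatnonzero(mask)
        n_drop = int(round(entry_missing * avail.size))
        dropped = rng.choice(avail, size=n_drop, replace=False)
        entry_mask.flat[dropped] = False
        mask.flat[dropped] = False

    design = [
        _one_hot(donor, n_donors, "donor"),
        _one_hot(pheno, 2, "phenotype"),
        _one_hot(tissue, n_tissues, "tissue"),
        _one_hot(
            inter, 2 * n_tissues, "phenotype:tissue", kind="interaction",
            level_ids=[f"p{p}:t{t}" for p in range(2) for t in range(n_tissues)],
        ),
    ]
    data = ExpressionMatrix(np.where(mask, Z, 0.0), mask)
    return SimulatedDataset(
        Z=data,
        truth=truth,
        design=design,
        truth_blocks={"D": D, "P": P, "T": T, "W": W, "V": V},
        noise_sd=delta,
        seed=seed,
        missing_rows=~row_kept,
        entry_mask=entry_mask,
    )


def rmse(A: np.ndarray, B: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root-mean-squared difference, optionally restricted to a mask."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    diff = A - B
    if mask is not None:
        diff = diff[np.asarray(mask, dtype=bool)]
    return float(np.sqrt(np.mean(diff**2)))


def baseline_rmse(truth: np.ndarray, Z: np.ndarray, train_mask: np.ndarray,
                  eval_mask: np.ndarray) -> float:
    """No-model reference: RMS difference between the true signal on the
    evaluation entries and the scalar mean of Z over the training entries."""
    zbar = float(np.mean(np.asarray(Z)[np.asarray(train_mask, dtype=bool)]))
    t = np.asarray(truth)[np.asarray(eval_mask, dtype=bool)]
    return float(np.sqrt(np.mean((t - zbar) ** 2)))


def _ridge_predict(X: np.ndarray, Z: np.ndarray, mask: np.ndarray,
                   lam: float) -> np.ndarray:
    """Per-gene ridge on the indicator predictors, honoring the entry mask."""
    n, p = X.shape
    m = Z.shape[1]
    XtX = X.T @ X
    G = np.broadcast_to(XtX, (m, p, p)).copy()
    if not mask.all():
        from .optimizer import _flat_outer

        W = (~mask).astype(float)
        G -= (W.T @ _flat_outer(X)).reshape(m, p, p)
    B = X.T @ np.where(mask, Z, 0.0)
    coefs = np.linalg.solve(G + lam * np.eye(p), B.T[:, :, None])[:, :, 0]
    return X @ coefs.T


def fit_ridge_baseline(Z: np.ndarray, X_E: np.ndarray, X_F: np.ndarray,
                       lambda_grid=(1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0),
                       train_mask: np.ndarray | None = None,
                       val_mask: np.ndarray | None = None) -> np.ndarray:
    """Ridge-regression comparator: per-gene ridge on the stacked indicator
    matrix [X_E X_F] with one shared penalty chosen by validation RMSE, then
    refit on train + validation entries.

    Returns the predicted signal matrix (same shape as Z).
    """
    Z = np.asarray(Z, dtype=float)
    X = np.hstack([X_E, X_F])
    if train_mask is None:
        train_mask = np.ones(Z.shape, dtype=bool)
    if val_mask is None:
        best_lam = lambda_grid[0]
    else:
        scores = []
        for lam in lambda_grid:
            pred = _ridge_predict(X, Z, train_mask, lam)
            scores.append((rmse(pred, Z, val_mask), -lam))
        best_lam = -min(scores)[1]
    refit_mask = train_mask | (val_mask if val_mask is not None else False)
    return _ridge_predict(X, Z, refit_mask, best_lam)


# ---------------------------------------------------------------------------
# Study harnesses: fit each generated design the way the validation studies
# prescribe, and score recovery of the noiseless signal.
# ---------------------------------------------------------------------------


def _fit_insider_fixed(data, design, K=5, lam=0.1, alpha=0.0, seed=0,
                       tol=1e-8, max_iter=300):
    hp = Hyperparams(K=K, ridge_lambda=lam, alpha=alpha, tol=tol,
                     max_iter=max_iter, seed=seed)
    return fit(data, design, hp)


def score_insider_design(delta: float, seed: int, interaction: bool = True,
                         K: int = 5, lam: float = 0.1) -> float:
    """Recovery RMSE (vs the noiseless signal, all entries) on the
    model-generated design, with or without the per-sample interaction."""
    sim = simulate_insider_design(delta, seed)
    design = list(sim.design)
    if interaction:
        design.append(observation_block(sim.Z.shape[0], name="interaction"))
    model = _fit_insider_fixed(sim.Z, design, K=K, lam=lam, seed=seed)
    return rmse(reconstruct(model), sim.truth)


def score_sda_design(sigma: float, seed: int, interaction: bool = True,
                     k_grid=range(2, 11), tune_iters: int = 30,
                     max_iter: int = 200) -> float:
    """Recovery RMSE on the trilinear design after hyperparameter selection
    on a 10% held-out entry split (rank grid, then {lambda, alpha} grid)."""
    sim = simulate_sda_design(sigma, seed)
    design = list(sim.design)
    if interaction:
        design.append(observation_block(sim.Z.shape[0], name="interaction"))
    model, _ = fit_with_selection(
        sim.Z, design, k_grid=k_grid,
        lambda_grid=DEFAULT_LAMBDA_GRID, alpha_grid=DEFAULT_ALPHA_GRID,
        seed=seed, tune_iters=tune_iters,
        final_hp=Hyperparams(tol=1e-8, max_iter=max_iter),
    )
    return rmse(reconstruct(model), sim.truth)


def score_linear_design(sigma: float, seed: int, k_grid=range(10, 31, 2),
                        tune_iters: int = 30,
                        methods=("insider", "ridge", "baseline")) -> dict:
    """The two-way linear design protocol: 10% hold-out entries, 10% of the
    rest for validation; tune on validation, refit on train + validation,
    score RMSE vs truth on the hold-out for the factor model, the per-gene
    ridge comparator, and the scalar-mean baseline."""
    sim = simulate_linear_design(sigma, seed)
    data = sim.Z
    rest_mask, holdout_mask = split_holdout(data, 0.1, seed)
    rest = ExpressionMatrix(data.values, rest_mask, data.sample_ids,
                            data.gene_ids)
    train_mask, val_mask = split_holdout(rest, 0.1, seed + 1)
    out: dict[str, float] = {}

    if "insider" in methods:
        # rank grid then {lambda, alpha} grid on the validation set
        model, _ = fit_with_selection(
            rest, sim.design, k_grid=k_grid, seed=seed, tune_iters=tune_iters,
            final_hp=Hyperparams(tol=1e-8, max_iter=200),
            refit_on_all=True,  # "all" here is train + validation (rest mask)
            split=(train_mask, val_mask),
        )
        out["insider"] = rmse(reconstruct(model), sim.truth, holdout_mask)

    if "ridge" in methods:
        X_E = sim.design[0].design
        X_F = sim.design[1].design
        pred = fit_ridge_baseline(data.values, X_E, X_F,
                                  train_mask=train_mask, val_mask=val_mask)
        out["ridge"] = rmse(pred, sim.truth, holdout_mask)

    if "baseline" in methods:
        out["baseline"] = baseline_rmse(sim.truth, data.values, rest_mask,
                                        holdout_mask)
    return out


def score_missing_design(delta: float, seed: int, pattern: str = "structured",
                         K: int = 5, lam: float = 0.1,
                         max_iter: int = 300) -> dict:
    """Fit the donor/phenotype/tissue design on its observed part and score
    recovery of the noiseless signal on missing entries and missing rows."""
    sim = simulate_missing_design(delta, pattern=pattern, seed=seed)
    data = sim.Z
    kept = ~sim.missing_rows if sim.missing_rows is not None else np.ones(
        data.shape[0], dtype=bool)
    sub = ExpressionMatrix(data.values[kept], data.mask[kept])
    sub_design = [
        replace(cov, design=cov.design[kept]) for cov in sim.design
    ]
    model = _fit_insider_fixed(sub, sub_design, K=K, lam=lam, seed=seed,
                               max_iter=max_iter)
    # predict all 400 rows from the full design matrices
    E_full = np.sum(
        [cov.design @ fac.values
         for cov, fac in zip(sim.design, (f for _, f in model.blocks))],
        axis=0,
    )
    pred = E_full @ model.loadings.values
    out: dict[str, float] = {}
    entry_missing_mask = kept[:, None] & ~sim.entry_mask
    if entry_missing_mask.any():
        out["missing_entries"] = rmse(pred, sim.truth, entry_missing_mask)
    if sim.missing_rows is not None and sim.missing_rows.any():
        row_mask = np.repeat(sim.missing_rows[:, None], data.shape[1], axis=1)
        out["missing_rows"] = rmse(pred, sim.truth, row_mask)
        out["baseline_rows"] = baseline_rmse(
            sim.truth, data.values, data.mask, row_mask
        )
    return out


def run_table(design_name: str, deltas=(0.25, 0.5, 0.75, 1.0),
              seeds=range(5), **kwargs) -> pd.DataFrame:
    """Run one validation design across noise levels and seeds.

    Returns a tidy DataFrame with one row per (delta, seed, metric) and the
    mean +/- sd summary is left to the caller (``df.groupby(...)``).
    """
    rows = []
    for delta in deltas:
        for seed in seeds:
            if design_name == "insider":
                rows.append((delta, seed, "with_interaction",
                             score_insider_design(delta, seed, True, **kwargs)))
                rows.append((delta, seed, "without_interaction",
                             score_insider_design(delta, seed, False, **kwargs)))
            elif design_name == "sda":
                rows.append((delta, seed, "with_interaction",
                             score_sda_design(delta, seed, True, **kwargs)))
            elif design_name == "linear":
                res = score_linear_design(delta, seed, **kwargs)
                for k, v in res.items():
                    rows.append((delta, seed, k, v))
            elif design_name == "missing":
                res = score_missing_design(delta, seed, **kwargs)
                for k, v in res.items():
                    rows.append((delta, seed, k, v))
            else:
                raise ValueError(f"unknown design '{design_name}'")
    return pd.DataFrame(rows, columns=["delta", "seed", "metric", "rmse"])
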