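"""Data model for covariate-aware additive matrix factorization.

The model decomposes an N-samples x M-genes expression matrix ``Z`` into a
sum of per-covariate low-rank contributions that share a single K x M gene
loading ("metagene") matrix ``V``::

    Z_hat = (sum_b X_b B_b) V

where each covariate block ``b`` contributes a design matrix ``X_b`` (one-hot
for categorical covariates and interactions, the identity for the per-sample
observation block, a single column of raw values for a continuous covariate)
and a levels x K latent factor matrix ``B_b``.  Missing entries in ``Z`` are
carried in an explicit boolean mask and never enter any sum.

The penalized least-squares objective is

    L = 1/2 sum_observed (z - z_hat)^2
      + lambda/2 * sum_b ||B_b||_F^2
      + lambda_1 * ( (1 - alpha)/2 * ||V||_F^2 + alpha * |V|_1 )

i.e. ridge on every covariate block (including the observation block) and an
elastic net on the gene loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CovariateBlock",
    "FactorBlock",
    "GeneLoadings",
    "Hyperparams",
    "ModelFit",
    "observation_block",
    "reconstruct",
    "objective",
]

BLOCK_KINDS = ("categorical", "interaction", "observation", "continuous")


class DimensionError(ValueError):
    """Shape mismatch between model components; names the offending block."""


@dataclass
class ExpressionMatrix:
    """Observed expression values with an explicit observed-entry mask."""

    values: np.ndarray
    mask: np.ndarray
    sample_ids: Sequence[str] | None = None
    gene_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise DimensionError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if self.values.ndim != 2:
            raise DimensionError("expression matrix must be 2-dimensional")
        n, m = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{j}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.gene_ids) != m:
            raise DimensionError("id lengths do not match matrix shape")

    @classmethod
    def from_values(cls, values, sample_ids=None, gene_ids=None) -> "ExpressionMatrix":
        """Build from a dense array; NaN entries become missing."""
        values = np.asarray(values, dtype=float)
        mask = np.isfinite(values)
        vals = np.where(mask, values, 0.0)
        return cls(vals, mask, sample_ids, gene_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


@dataclass
class CovariateBlock:
    """One covariate's design matrix: N x L indicator (or raw-value) matrix."""

    name: str
    design: np.ndarray
    kind: str = "categorical"
    level_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise DimensionError(f"block '{self.name}': design must be 2-d")
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"block '{self.name}': unknown kind '{self.kind}'")
        if self.level_ids is None:
            self.level_ids = [f"{self.name}_{i}" for i in range(self.design.shape[1])]
        if len(self.level_ids) != self.design.shape[1]:
            raise DimensionError(f"block '{self.name}': level_ids length mismatch")
        if self.kind in ("categorical", "interaction", "observation"):
            d = self.design
            is_indicator = np.all((d == 0) | (d == 1)) and np.all(d.sum(axis=1) == 1)
            if not is_indicator:
                raise ValueError(
                    f"block '{self.name}': {self.kind} design must be one-hot "
                    "(exactly one 1 per row)"
                )

    @property
    def n_levels(self) -> int:
        return self.design.shape[1]

    @property
    def level_index(self) -> np.ndarray:
        """Per-sample level assignment (argmax of the one-hot rows)."""
        if self.kind == "continuous":
            raise ValueError(f"block '{self.name}' is continuous; no level index")
        return np.argmax(self.design, axis=1)


@dataclass
class FactorBlock:
    """Levels x K latent representation for one covariate block."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(f"factor block '{self.name}' must be 2-d")

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneLoadings:
    """Shared K x M metagene matrix; row k is metagene k across all genes."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("gene loadings must be 2-d (K x M)")

    @property
    def k(self) -> int:
        return self.values.shape[0]


@dataclass
class Hyperparams:
    """Tuning parameters {K, lambda, alpha} plus optimizer controls.

    ``enet_lambda`` is the weight of the elastic-net penalty on V; it defaults
    to ``ridge_lambda`` (the two appear as a single lambda in the tuning
    interface).
    """

    K: int = 10
    ridge_lambda: float = 0.1
    enet_lambda: float | None = None
    alpha: float = 0.0
    tol: float = 1e-10
    max_iter: int = 500
    seed: int = 0
    init_sd: float = 0.001

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.enet_lambda is None:
            self.enet_lambda = self.ridge_lambda


@dataclass
class ModelFit:
    """A fitted model: covariate blocks with factors, loadings, bookkeeping."""

    blocks: list[tuple[CovariateBlock, FactorBlock]]
    loadings: GeneLoadings
    hyperparams: Hyperparams
    loss_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    def block(self, name: str) -> tuple[CovariateBlock, FactorBlock]:
        for cov, fac in self.blocks:
            if cov.name == name:
                return cov, fac
        raise KeyError(f"no covariate block named '{name}'")

    @property
    def block_names(self) -> list[str]:
        return [cov.name for cov, _ in self.blocks]


def observation_block(n: int, name: str = "observation") -> CovariateBlock:
    """The N x N identity design: one free latent row per sample."""
    return CovariateBlock(name=name, design=np.eye(n), kind="observation")


def _check_conformable(fit: ModelFit, n: int | None = None) -> None:
    k = fit.loadings.k
    for cov, fac in fit.blocks:
        if fac.values.shape[0] != cov.design.shape[1]:
            raise DimensionError(
                f"block '{cov.name}': design has {cov.design.shape[1]} levels "
                f"but factor matrix has {fac.values.shape[0]} rows"
            )
        if fac.values.shape[1] != k:
            raise DimensionError(
                f"block '{cov.name}': factor K={fac.values.shape[1]} != loadings K={k}"
            )
        if n is not None and cov.design.shape[0] != n:
            raise DimensionError(
                f"block '{cov.name}': design has {cov.design.shape[0]} rows, "
                f"expected {n}"
            )


def scores(fit: ModelFit) -> np.ndarray:
    """N x K combined predictor matrix E = sum_b X_b B_b."""
    _check_conformable(fit)
    total = None
    for cov, fac in fit.blocks:
        contrib = cov.design @ fac.values
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("model has no covariate blocks")
    return total


def reconstruct(fit: ModelFit) -> np.ndarray:
    """Full N x M reconstruction Z_hat = (sum_b X_b B_b) V, ignoring any mask."""
    return scores(fit) @ fit.loadings.values


def penalty(fit: ModelFit) -> float:
    """Ridge + elastic-net penalty terms of the objective."""
    hp = fit.hyperparams
    ridge = 0.5 * hp.ridge_lambda * sum(
        float(np.sum(fac.values**2)) for _, fac in fit.blocks
    )
    v = fit.loadings.values
    enet = hp.enet_lambda * (
        0.5 * (1.0 - hp.alpha) * float(np.sum(v**2))
        + hp.alpha * float(np.sum(np.abs(v)))
    )
    return ridge + enet


def objective(fit: ModelFit, data: ExpressionMatrix) -> float:
    """Penalized squared-error objective; only observed entries enter the fit term."""
    _check_conformable(fit, n=data.shape[0])
    zhat = reconstruct(fit)
    resid = np.where(data.mask, data.values - zhat, 0.0)
    return 0.5 * float(np.sum(resid**2)) + penalty(fit)
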