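"""Alternating block coordinate descent for the additive factor model.

Each outer iteration updates, in order: every categorical/interaction block
(declaration order), the per-sample observation block if present, continuous
blocks, and finally the gene-loading matrix V.  Every covariate-block update
is an exact masked ridge solve of its normal equations; the V update solves
each gene's elastic-net subproblem (closed form when alpha = 0, randomized
coordinate descent with safe screening otherwise).  Because every step is an
exact (or KKT-converged, warm-started) minimizer of its subproblem, the
objective is non-increasing across updates.

Missing entries are honored exactly: for rows with unobserved genes the Gram
matrix V V' is accumulated only over that sample's observed gene columns, and
likewise E'E per gene over that gene's observed samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._enet import cd_enet
from ._segsum import segment_sum
from .factor_model import (
    CovariateBlock,
    ExpressionMatrix,
    FactorBlock,
    GeneLoadings,
    Hyperparams,
    ModelFit,
    reconstruct,
)

__all__ = [
    "ResidualTarget",
    "ScreeningReport",
    "update_categorical_block",
    "update_observation_block",
    "update_continuous_block",
    "update_gene_loadings",
    "screen",
    "fit",
    "holdout_rmse",
]

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps

SINGULAR_HINT = (
    "singular system in block update; set ridge_lambda > 0 "
    "(e.g. 0.1) to avoid singularity in matrix inverse"
)


@dataclass
class ResidualTarget:
    """Z-tilde: data minus the reconstruction of all blocks except one."""

    values: np.ndarray
    mask: np.ndarray

    def masked(self) -> np.ndarray:
        return np.where(self.mask, self.values, 0.0)


@dataclass
class ScreeningReport:
    """Outcome of the safe screening rule for one gene's column solve."""

    gene_index: int
    discarded: set = field(default_factory=set)
    lambda_max: float = 0.0


def _flat_outer(A: np.ndarray) -> np.ndarray:
    """Row-wise outer products of an n x K matrix, flattened to n x K^2."""
    n, k = A.shape
    return (A[:, :, None] * A[:, None, :]).reshape(n, k * k)


def _level_grams(V: np.ndarray, mask: np.ndarray, lev_idx: np.ndarray,
                 n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level sums of masked Grams sum_{s in level} V diag(m_s) V'.

    Uses the complement trick: count * VV' minus the per-level missing-entry
    correction C @ VV, where C[l, m] counts level l's missing entries of
    gene m and VV stacks the loadings' columnwise outer products.  The
    correction is a single BLAS matmul, cheap when the mask is dense.
    Returns (n_levels x K x K Gram stack, observed-entry count per level).
    """
    K = V.shape[0]
    counts = np.bincount(lev_idx, minlength=n_levels).astype(float)
    VVt = V @ V.T
    G = counts[:, None, None] * VVt
    obs_per_sample = mask.sum(axis=1)
    lev_obs = np.bincount(lev_idx, weights=obs_per_sample, minlength=n_levels)
    if not mask.all():
        W = (~mask).astype(float)
        C = segment_sum(W, lev_idx, n_levels)
        G -= (C @ _flat_outer(V.T)).reshape(n_levels, K, K)
    return G, lev_obs


def _solve_levels(G: np.ndarray, rhs: np.ndarray, lam: float,
                  lev_obs: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """Batched ridge solve per level; levels with no observed data keep prev."""
    K = rhs.shape[1]
    A = G + lam * np.eye(K)
    try:
        sol = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(SINGULAR_HINT) from exc
    empty = lev_obs == 0
    if empty.any():
        sol[empty] = prev[empty]
    return sol


def update_categorical_block(
    block_pair: tuple[CovariateBlock, FactorBlock],
    residual: ResidualTarget,
    V: GeneLoadings,
    lam: float,
) -> FactorBlock:
    """Exact masked ridge update for a categorical/interaction block.

    Each level's row solves  (sum_{s in S_l} V diag(m_s) V' + lam I) b_l =
    sum_{s in S_l} V (m_s * ztilde_s).  Levels with zero observed entries are
    left at their previous value.
    """
    cov, fac = block_pair
    Vv = V.values
    lev_idx = cov.level_index
    L = cov.n_levels
    Rm = residual.masked()
    G, lev_obs = _level_grams(Vv, residual.mask, lev_idx, L)
    rhs = segment_sum(Rm @ Vv.T, lev_idx, L)
    new = _solve_levels(G, rhs, lam, lev_obs, fac.values)
    return FactorBlock(cov.name, new)


def update_observation_block(
    residual: ResidualTarget,
    V: GeneLoadings,
    lam: float,
    prev: FactorBlock | None = None,
    name: str = "observation",
) -> FactorBlock:
    """Per-sample ridge update u_s = (V diag(m_s) V' + lam I)^{-1} V ztilde_s."""
    n = residual.values.shape[0]
    Vv = V.values
    lev_idx = np.arange(n)
    prev_vals = prev.values if prev is not None else np.zeros((n, Vv.shape[0]))
    G, lev_obs = _level_grams(Vv, residual.mask, lev_idx, n)
    rhs = residual.masked() @ Vv.T
    new = _solve_levels(G, rhs, lam, lev_obs, prev_vals)
    return FactorBlock(prev.name if prev is not None else name, new)


def update_continuous_block(
    q_pair: tuple[CovariateBlock, FactorBlock],
    residual: ResidualTarget,
    V: GeneLoadings,
    lam: float,
) -> FactorBlock:
    """Closed-form update for a continuous covariate's 1 x K representation.

    q = (sum_s x_s^2 V diag(m_s) V' + lam I)^{-1} V (masked Ztilde)' x
    """
    cov, fac = q_pair
    x = cov.design[:, 0]
    Vv = V.values
    K = Vv.shape[0]
    mask = residual.mask
    VVt = Vv @ Vv.T
    G = float(np.sum(x**2)) * VVt
    if not mask.all():
        c = (x**2) @ (~mask).astype(float)  # per-gene weighted miss counts
        G -= (Vv * c) @ Vv.T
    rhs = Vv @ (residual.masked().T @ x)
    try:
        q = np.linalg.solve(G + lam * np.eye(K), rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(SINGULAR_HINT) from exc
    return FactorBlock(cov.name, q[None, :])


def screen(E: np.ndarray, Z_m: np.ndarray, lam1: float, alpha: float,
           gene_index: int = 0) -> ScreeningReport:
    """Screening rule for one gene's column solve.

    Discards predictor j when |e_j' Z_m| < alpha (2 lam - lam_max) with
    lam_max = max_j |e_j' Z_m| (strict inequality); vacuous when the
    threshold is nonpositive (in particular at alpha = 0).  Screened solves
    are always followed by a KKT check so the final solution is identical to
    the unscreened one.
    """
    corr = np.abs(E.T @ Z_m)
    lam_max = float(corr.max()) if corr.size else 0.0
    thr = alpha * (2.0 * lam1 - lam_max)
    report = ScreeningReport(gene_index=gene_index, lambda_max=lam_max)
    if thr > 0.0:
        report.discarded = set(np.nonzero(corr < thr)[0].tolist())
    return report


def _gene_grams(E: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene Gram stack G_m = E' diag(mask[:, m]) E via complement trick."""
    M = mask.shape[1]
    K = E.shape[1]
    EtE = E.T @ E
    G = np.broadcast_to(EtE, (M,) + EtE.shape).copy()
    if not mask.all():
        W = (~mask).astype(float)
        G -= (W.T @ _flat_outer(E)).reshape(M, K, K)
    return G


def update_gene_loadings(
    E: np.ndarray,
    data: ExpressionMatrix,
    lam1: float,
    alpha: float,
    V_prev: GeneLoadings,
    seed: int = 0,
    use_screening: bool = True,
    kkt_tol: float = 1e-8,
    max_sweeps: int = 200,
) -> tuple[GeneLoadings, list[ScreeningReport]]:
    """Solve every gene's elastic-net subproblem sharing the predictor E.

    alpha = 0 reduces to a batched closed-form ridge solve.  Otherwise each
    column runs randomized coordinate descent (RNG stream seeded per gene
    index so parallel and sequential execution agree), restricted to the
    coordinates surviving the screening rule, followed by a KKT check that
    re-admits and re-solves any violating coordinate.
    """
    K = E.shape[1]
    M = data.shape[1]
    mask = data.mask
    Zf = np.where(mask, data.values, 0.0)
    B = E.T @ Zf  # K x M correlation vectors (masked rows contribute 0)
    G = _gene_grams(E, mask)
    l2 = lam1 * (1.0 - alpha)
    l1 = lam1 * alpha
    reports: list[ScreeningReport] = []

    if alpha == 0.0:
        A = G + lam1 * np.eye(K)
        try:
            V = np.linalg.solve(A, B.T[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(SINGULAR_HINT) from exc
        # genes with no observed entries get a zero column
        gene_obs = mask.sum(axis=0)
        V[:, gene_obs == 0] = 0.0
        return GeneLoadings(V), reports

    V = V_prev.values.copy()
    gene_obs = mask.sum(axis=0)
    for m in range(M):
        if gene_obs[m] == 0:
            V[:, m] = 0.0
            reports.append(ScreeningReport(gene_index=m))
            continue
        b = B[:, m]
        corr = np.abs(b)
        lam_max = float(corr.max())
        rep = ScreeningReport(gene_index=m, lambda_max=lam_max)
        thr = alpha * (2.0 * lam1 - lam_max)
        discard = (
            corr < thr if (use_screening and thr > 0.0)
            else np.zeros(K, dtype=bool)
        )
        rng = np.random.default_rng([seed, m])
        v = V[:, m]
        v[discard] = 0.0
        while True:
            act = np.nonzero(~discard)[0].astype(np.int64)
            if act.size:
                # randomized order drawn in chunks: warm-started columns
                # typically converge within the first few sweeps
                sweeps_left = max_sweeps
                while sweeps_left > 0:
                    chunk = min(25, sweeps_left)
                    order = rng.integers(
                        0, act.size, size=chunk * act.size
                    ).astype(np.int64)
                    converged = cd_enet(G[m], b, v, act, l1, l2, order,
                                        kkt_tol * 0.1)
                    sweeps_left -= chunk
                    if converged:
                        break
            # re-admit screened coordinates that violate the KKT conditions
            g = G[m] @ v - b
            viol = discard & (np.abs(g) > l1 + kkt_tol)
            if not viol.any():
                break
            discard &= ~viol
        rep.discarded = set(np.nonzero(discard & (v == 0.0))[0].tolist())
        reports.append(rep)
        V[:, m] = v
    return GeneLoadings(V), reports


def _contribution(cov: CovariateBlock, fac_values: np.ndarray) -> np.ndarray:
    if cov.kind == "observation":
        return fac_values
    if cov.kind == "continuous":
        return cov.design[:, 0][:, None] * fac_values[0][None, :]
    return fac_values[cov.level_index]


def _data_term(Zf: np.ndarray, mask: np.ndarray, total: np.ndarray,
               V: np.ndarray) -> float:
    resid = Zf - total @ V
    resid[~mask] = 0.0
    return 0.5 * float(np.sum(resid**2))


def fit(
    data: ExpressionMatrix,
    design: list[CovariateBlock],
    hp: Hyperparams,
    use_screening: bool = True,
) -> ModelFit:
    """Fit the model by alternating block coordinate descent.

    Stops when the relative objective change |L_i - L_{i-1}| / |L_{i-1}|
    drops below ``hp.tol`` (tested from the second iteration on) or at
    ``hp.max_iter``.  All factor matrices are initialized from N(0, init_sd)
    using ``hp.seed``; the run is deterministic given the seed.
    """
    if not design:
        raise ValueError("empty design: at least one covariate block required")
    n, m = data.shape
    for cov in design:
        if cov.design.shape[0] != n:
            raise ValueError(
                f"block '{cov.name}' has {cov.design.shape[0]} rows, data has {n}"
            )
    rng = np.random.default_rng(hp.seed)
    K = hp.K
    factors = [rng.normal(0.0, hp.init_sd, size=(cov.n_levels, K))
               for cov in design]
    V = rng.normal(0.0, hp.init_sd, size=(K, m))

    # update order: categorical/interaction (declaration order), observation,
    # continuous, then V
    order = (
        [i for i, c in enumerate(design) if c.kind in ("categorical", "interaction")]
        + [i for i, c in enumerate(design) if c.kind == "observation"]
        + [i for i, c in enumerate(design) if c.kind == "continuous"]
    )

    mask = data.mask
    Zf = np.where(mask, data.values, 0.0)
    contribs = [_contribution(cov, fac) for cov, fac in zip(design, factors)]
    total = np.sum(contribs, axis=0)
    loadings = GeneLoadings(V)

    ridge_pen = lambda: 0.5 * hp.ridge_lambda * sum(
        float(np.sum(f**2)) for f in factors
    )
    enet_pen = lambda: hp.enet_lambda * (
        0.5 * (1.0 - hp.alpha) * float(np.sum(loadings.values**2))
        + hp.alpha * float(np.sum(np.abs(loadings.values)))
    )

    loss_trace: list[float] = []
    n_iter = 0
    for it in range(1, hp.max_iter + 1):
        n_iter = it
        for bi in order:
            cov = design[bi]
            other = total - contribs[bi]
            resid = ResidualTarget(Zf - other @ loadings.values, mask)
            pair = (cov, FactorBlock(cov.name, factors[bi]))
            if cov.kind == "observation":
                newfac = update_observation_block(
                    resid, loadings, hp.ridge_lambda, prev=pair[1]
                )
            elif cov.kind == "continuous":
                newfac = update_continuous_block(
                    pair, resid, loadings, hp.ridge_lambda
                )
            else:
                newfac = update_categorical_block(
                    pair, resid, loadings, hp.ridge_lambda
                )
            factors[bi] = newfac.values
            contribs[bi] = _contribution(cov, factors[bi])
            total = other + contribs[bi]
        loadings, _ = update_gene_loadings(
            total, data, hp.enet_lambda, hp.alpha, loadings,
            seed=hp.seed, use_screening=use_screening,
        )
        loss = _data_term(Zf, mask, total, loadings.values) + ridge_pen() + enet_pen()
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        loss_trace.append(loss)
        logger.info("iter %d: objective %.6g", it, loss)
        if it >= 2:
            prev = loss_trace[-2]
            rel = abs(loss - prev) / max(abs(prev), _EPS)
            if rel < hp.tol:
                break

    blocks = [
        (cov, FactorBlock(cov.name, fac)) for cov, fac in zip(design, factors)
    ]
    return ModelFit(
        blocks=blocks,
        loadings=loadings,
        hyperparams=hp,
        loss_trace=loss_trace,
        n_iter=n_iter,
    )


def holdout_rmse(fit_: ModelFit, data: ExpressionMatrix,
                 holdout_mask: np.ndarray) -> float:
    """RMSE between data and reconstruction over held-out entries."""
    holdout_mask = np.asarray(holdout_mask, dtype=bool)
    if not holdout_mask.any():
        raise ValueError("empty holdout mask")
    zhat = reconstruct(fit_)
    diff = data.values[holdout_mask] - zhat[holdout_mask]
    return float(np.sqrt(np.mean(diff**2)))
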