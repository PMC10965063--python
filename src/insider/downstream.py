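"""Post-fit interpretation utilities.

Adjusted expression profiles isolate the expression attributable to one
covariate (e.g. developmental stage, tissue, phenotype) by multiplying that
covariate's factor matrix with the shared gene loadings, with every other
covariate's variation controlled.  Metagenes can be ranked by their variance
across a block's levels, low-variance metagenes excluded, level contrasts
formed, and extreme-quantile gene sets exported for external enrichment
analysis.
"""

from __future__ import annotations

import numpy as np

from .factor_model import ModelFit, reconstruct

__all__ = [
    "adjusted_expression",
    "metagene_variance_ranking",
    "exclude_low_variance_metagenes",
    "interaction_profile",
    "contrast_profile",
    "quantile_gene_sets",
]


def _metagene_subset(fit: ModelFit, include) -> np.ndarray:
    K = fit.loadings.k
    if include is None:
        return np.arange(K)
    idx = np.asarray(sorted(include), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= K):
        raise IndexError(f"metagene index out of range 0..{K - 1}")
    return idx


def adjusted_expression(fit: ModelFit, block_name: str,
                        include_metagenes=None) -> np.ndarray:
    """Levels x genes expression attributable to one covariate block:
    B[:, S] V[S, :] for the selected metagene subset S (default all)."""
    _, fac = fit.block(block_name)
    S = _metagene_subset(fit, include_metagenes)
    if S.size == 0:
        return np.zeros((fac.values.shape[0], fit.loadings.values.shape[1]))
    return fac.values[:, S] @ fit.loadings.values[S, :]


def metagene_variance_ranking(fit: ModelFit,
                              block_name: str) -> list[tuple[int, float]]:
    """Metagenes ordered by descending variance across the block's levels."""
    _, fac = fit.block(block_name)
    variances = np.var(fac.values, axis=0)
    order = np.argsort(-variances, kind="stable")
    return [(int(k), float(variances[k])) for k in order]


def exclude_low_variance_metagenes(fit: ModelFit, block_name: str,
                                   n_exclude: int) -> list[int]:
    """Metagene subset with the n_exclude lowest-variance metagenes removed."""
    ranking = metagene_variance_ranking(fit, block_name)
    if not 0 <= n_exclude <= len(ranking):
        raise ValueError("n_exclude must lie in [0, K]")
    kept = ranking[: len(ranking) - n_exclude]
    return sorted(k for k, _ in kept)


def interaction_profile(fit: ModelFit, level_selector,
                        block_name: str = "phenotype:tissue",
                        include_metagenes=None) -> np.ndarray:
    """One interaction level's adjusted profile: W_k[S] V[S, :].

    ``level_selector`` is a level id (string) or integer row index into the
    interaction block.
    """
    cov, fac = fit.block(block_name)
    if isinstance(level_selector, str):
        try:
            row = list(cov.level_ids).index(level_selector)
        except ValueError:
            raise KeyError(
                f"level '{level_selector}' not in block '{block_name}'"
            ) from None
    else:
        row = int(level_selector)
    profile = adjusted_expression(fit, block_name, include_metagenes)
    return profile[row]


def contrast_profile(fit: ModelFit, block_name: str, level_a, level_b,
                     include_metagenes=None) -> np.ndarray:
    """Difference of two levels' adjusted profiles: (B[a,S] - B[b,S]) V[S,:]."""
    cov, _ = fit.block(block_name)
    ids = list(cov.level_ids)
    ia = ids.index(level_a) if isinstance(level_a, str) else int(level_a)
    ib = ids.index(level_b) if isinstance(level_b, str) else int(level_b)
    profile = adjusted_expression(fit, block_name, include_metagenes)
    return profile[ia] - profile[ib]


def quantile_gene_sets(profile: np.ndarray, q: float = 0.025,
                       gene_ids=None) -> tuple[list, list]:
    """Genes in the upper and lower q-quantile tails of a profile.

    Each tail has exactly ceil(q * M) genes; ties are broken by gene order
    (stable sort).  Returns (upper set, lower set) as gene ids.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie strictly between 0 and 0.5")
    profile = np.asarray(profile).ravel()
    m = profile.size
    n_tail = int(np.ceil(q * m))
    if gene_ids is None:
        gene_ids = list(range(m))
    order = np.argsort(profile, kind="stable")
    lower = sorted(order[:n_tail].tolist())
    upper = sorted(order[m - n_tail:].tolist())
    return [gene_ids[i] for i in upper], [gene_ids[i] for i in lower]
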