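"""Grouped summation via sort + reduceat (much faster than ufunc.at)."""

from __future__ import annotations

import numpy as np


def segment_sum(values: np.ndarray, groups: np.ndarray,
                n_groups: int) -> np.ndarray:
    """Sum ``values`` (n x ...) into ``n_groups`` buckets along axis 0."""
    out = np.zeros((n_groups,) + values.shape[1:], dtype=float)
    if groups.size == 0:
        return out
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    v = values[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    out[g[starts]] = np.add.reduceat(v, starts, axis=0)
    return out
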