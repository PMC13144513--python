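"""Small statistical helpers shared by several pipeline stages."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "robust_z"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values for one testing family.

    NaN entries (untestable hypotheses) are passed through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def robust_z(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Median/MAD z-scores with the 1.4826 Gaussian-consistency constant.

    Entries where the MAD is zero come back as NaN (the caller decides how to
    record the skipped protein).  NaN inputs propagate.
    """
    x = np.asarray(values, dtype=float)
    med = np.nanmedian(x, axis=axis, keepdims=True)
    mad = np.nanmedian(np.abs(x - med), axis=axis, keepdims=True)
    scale = 1.4826 * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - med) / scale
    z = np.where(np.broadcast_to(scale, z.shape) == 0, np.nan, z)
    return z
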