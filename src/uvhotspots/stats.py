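"""Shared statistical helpers (multiple-testing correction)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    This is the single FDR implementation used by every module, delegating
    to :func:`statsmodels.stats.multitest.multipletests` (``fdr_bh``), whose
    adjusted p-values equal the definitional step-up quantity
    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
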