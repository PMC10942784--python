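"""Shared statistical helpers."""
from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through untouched; the adjustment is computed
    over the finite entries only.  Values outside [0, 1] are an error.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    if finite.any():
        vals = p[finite]
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[finite] = multipletests(vals, method="fdr_bh")[1]
    return out
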