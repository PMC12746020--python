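"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def z_to_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal-tail p-value for a z statistic (NaN passes through)."""
    z = np.asarray(z, dtype=float)
    p = np.full(z.shape, np.nan)
    ok = np.isfinite(z)
    p[ok] = np.minimum(2.0 * sps.norm.sf(np.abs(z[ok])), 1.0)
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    NaN entries (untestable hypotheses) are excluded from the family and
    returned as NaN; the family is the finite entries only.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
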