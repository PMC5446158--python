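"""Flowering volume: area under the 12-month FP curve.

The volume of one plot's flowering-potential profile is the trapezoidal
area under FP versus month index (unit spacing, January through
December, no extrapolation past the end months). On the percent-cover
scale a constant 100% profile bounds the volume at 1100 %-months.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cover import KEY_COLS
from .fp import FPMatrix
from .traits import MONTHS

MAX_VOLUME = 1100.0  # 11 intervals x 100% cover


def trapezoid_auc(fp_by_month) -> float:
    """Trapezoidal area under 12 ordered monthly values (unit spacing)."""
    v = np.asarray(fp_by_month, dtype=float)
    if v.shape != (12,):
        raise ValueError(f"expected exactly 12 monthly values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("FP values must be finite")
    if np.any(v < 0):
        raise ValueError("FP values must be non-negative")
    return float(np.trapezoid(v))


def plot_volumes(matrix: FPMatrix) -> pd.DataFrame:
    """Per-plot flowering volume on the percent scale (%-cover x months)."""
    vals = 100.0 * matrix.frame[list(MONTHS)].to_numpy()
    volumes = [trapezoid_auc(row) for row in vals]
    out = matrix.frame[KEY_COLS].copy()
    out["volume_pct_month"] = volumes
    return out
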