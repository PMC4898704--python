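"""Histogram binning by the Freedman-Diaconis rule."""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["freedman_diaconis_bins"]


def freedman_diaconis_bins(sample) -> np.ndarray:
    """Bin edges with width 2 * IQR * n^(-1/3), spanning the sample.

    The interquartile range uses midpoint quantiles (quartiles halfway
    between the bracketing order statistics).  A zero IQR falls back to
    the square-root rule; a constant sample gets a single unit-width bin.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return np.array([lo - 0.5, hi + 0.5])
    q25, q75 = np.percentile(x, [25, 75], method="midpoint")
    iqr = q75 - q25
    if iqr > 0:
        width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    else:
        width = (hi - lo) / np.ceil(np.sqrt(x.size))
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    return lo + width * np.arange(n_bins + 1)
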