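"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["empirical_pvalue"]


def empirical_pvalue(observed: float, null_values) -> float:
    """Add-one-smoothed one-sided empirical p: (1 + #{null >= obs}) / (1 + n).

    The smoothing counts the observed statistic as one draw from its own
    null, so the p-value is never exactly 0.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((1.0 + np.count_nonzero(null >= observed)) / (1.0 + null.size))
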