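"""Small shared helpers."""

from __future__ import annotations

import math

__all__ = ["aicc"]


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 l + 2k + 2k(k+1)/(n-k-1); infinite when the correction
    denominator is non-positive.
    """
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
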