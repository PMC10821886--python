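"""Diversity metrics for community states.

The package's headline diversity measure is the exponential Shannon index
(the Hill number of order 1): H = exp(-sum_i q_i ln q_i) with q_i the
relative abundances. It reads as an effective species count: H = m for m
equally abundant species, H = 1 for a monoculture. Natural logarithms are
used throughout (the base cancels in exp(entropy) only when log and exp
share it).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = ["shannon_index", "survivor_count"]


def shannon_index(abundances) -> float:
    """Exponential Shannon index (effective species number) of an abundance vector.

    Zero-abundance entries contribute nothing (the x*ln(x) -> 0 limit);
    the index is scale-invariant and lies in [1, m]. An all-zero vector has
    no defined diversity and raises.
    """
    s = np.atleast_1d(np.asarray(abundances, dtype=float))
    if np.any(s < 0):
        raise ParameterError("abundances must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ParameterError("diversity undefined for a community with zero total abundance")
    q = s[s > 0] / total
    q = q[q > 0]  # guard against underflow of extreme abundance ratios
    return float(np.exp(-np.sum(q * np.log(q))))


def survivor_count(abundances, threshold: float = 0.01) -> int:
    """Number of species above the survival threshold (default 0.01)."""
    s = np.atleast_1d(np.asarray(abundances, dtype=float))
    return int(np.count_nonzero(s > threshold))
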