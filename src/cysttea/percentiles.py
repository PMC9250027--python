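"""Nearest-rank percentile selection shared by the query and reference stages.

The pipeline selects "highly expressed" proteins as those at or above a
percentile cutoff of an expression distribution. The cutoff is the
nearest-rank threshold: for q in (0, 100] over m detected values sorted
ascending, the threshold is the value at rank ceil(q/100 * m). All values
at exactly the threshold are selected (inclusive tie policy), so the
selection is deterministic and needs no interpolation convention.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import RangeError, UsageError


def nearest_rank_threshold(values: np.ndarray, percentile_q: float) -> float:
    """Threshold value at nearest rank ceil(q/100 * m) of ascending `values`.

    `values` must be the *detected* observations only (no NaN); zeros are
    legitimate detected-absent measurements and participate.
    """
    if not 0.0 < percentile_q <= 100.0:
        raise RangeError(f"percentile must be in (0, 100], got {percentile_q}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UsageError("cannot take a percentile of an empty distribution")
    if np.isnan(values).any():
        raise UsageError("missing values must be removed before ranking")
    rank = math.ceil(percentile_q / 100.0 * values.size)  # 1-based
    return float(np.sort(values)[rank - 1])


def select_at_or_above(values: np.ndarray, percentile_q: float) -> np.ndarray:
    """Boolean mask of values >= the nearest-rank threshold."""
    threshold = nearest_rank_threshold(values, percentile_q)
    return np.asarray(values, dtype=float) >= threshold
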