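"""Summary statistics shared by the feature families.

The four-number summary (mean, population standard deviation, min/max
ratio, disorder) is applied to every per-patch measurement set in the
architecture families; the shape family aggregates per-nucleus
descriptors with {mean, std, median, min/max ratio}.

The disorder statistic is 1 - 1/(1 + sigma/mu) = sigma/(mu + sigma): it
is 0 for a perfectly regular measurement set and approaches 1 as the
coefficient of variation grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucmorph.errors import UndefinedFeatureError


@dataclass(frozen=True)
class StatSet:
    mean: float
    std: float
    minmax_ratio: float
    disorder: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mean, self.std, self.minmax_ratio, self.disorder)


def minmax_ratio(values: np.ndarray) -> float:
    """min/max of the measurement magnitudes; 1.0 when all values are zero.

    Computed on absolute values so that it coincides with min/max for
    the non-negative measurements the architecture families produce
    while staying bounded in [0, 1] for signed shape descriptors.
    """
    mags = np.abs(values)
    vmax = float(np.max(mags))
    vmin = float(np.min(mags))
    # a measurement set equal up to rounding noise is a constant set
    if vmax - vmin <= 1e-12 * max(vmax, 1.0):
        return 1.0
    return vmin / vmax


def disorder(values: np.ndarray) -> float:
    """sigma / (mu + sigma) with population sigma; 0 when the mean is 0."""
    mu = float(np.mean(values))
    sigma = float(np.std(values))
    if mu == 0.0:
        return 0.0
    return sigma / (mu + sigma)


def statset(values) -> StatSet:
    """Four-number summary of a non-empty measurement set.

    Raises
    ------
    UndefinedFeatureError
        If the input is empty.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise UndefinedFeatureError("statset of an empty measurement set")
    return StatSet(
        mean=float(np.mean(arr)),
        std=float(np.std(arr)),
        minmax_ratio=minmax_ratio(arr),
        disorder=disorder(arr),
    )
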