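"""MPF-to-myelin-density calibration and derived effect measures.

MPF tracks myelin content linearly; histological validation gives the
calibration ``MPF = slope * MD + intercept`` with ``slope = 0.21`` and
``intercept = 3.9`` (both in percent units), where MD is the myelin
density by histological staining.  Inverting the line converts tissue
mean MPF to an estimated myelin density.  The module also provides the
standard derived group-contrast measures: percentage decrease relative to
a reference group and Cohen's d by pooled standard deviation.

Reporting conventions: myelin densities are rounded to one decimal and
relative MPF decreases to the nearest integer in summaries; raw values
are always returned unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CalibrationLine",
    "mpf_to_myelin_density",
    "percent_change",
    "cohens_d",
]


@dataclass(frozen=True)
class CalibrationLine:
    """Linear MPF-myelin-density relationship, percent units both sides."""

    slope: float = 0.21
    intercept: float = 3.9

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


def mpf_to_myelin_density(mpf: float, line: CalibrationLine | None = None) -> float:
    """Estimated myelin density (percent) from a mean MPF (percent).

    ``MD = (MPF - intercept) / slope``.  Values below the intercept
    extrapolate to negative densities; they are returned as-is (the caller
    may treat them as out of calibration range).
    """
    if line is None:
        line = CalibrationLine()
    return (mpf - line.intercept) / line.slope


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Relative decrease of ``comparison`` vs ``reference``, in percent.

    ``100 * (reference - comparison) / reference``; positive when the
    comparison group is lower.
    """
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean must be nonzero")
    return 100.0 * (reference_mean - comparison_mean) / reference_mean


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Cohen's d: mean difference over the pooled standard deviation.

    ``s_p = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))``; the
    sign convention is group 1 (reference) minus group 2 (comparison).
    Equal groups with zero pooled SD return ``inf`` with the sign of the
    mean difference (0 for equal means).
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s_p = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                    / (n1 + n2 - 2))
    diff = mean1 - mean2
    if s_p == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / s_p
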