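"""Published reference values for green-tea fixation monitoring.

The original study of this algorithm reports, for roller fixation of
Wu Niu Zao green tea at 220 °C, the trained cluster centers of the three
colour channels at fixation times of 2, 4, 6 and 8 min (in normalised
plotting units), together with the pairwise center distances and their
sum.  These numbers serve as frozen ground truth for validation: feeding
the centers through :func:`ieamsc.monitor.pairwise_center_distances`
should recover the distance table, and the distance sums shrink strictly
with fixation time (the "shrinking triangle").
"""

from __future__ import annotations

from .attention import Point

__all__ = [
    "FIXATION_TIMES_MIN",
    "REFERENCE_CENTERS",
    "REFERENCE_DISTANCES",
    "STANDARD_TIME_MIN",
    "REFERENCE_ALPHA",
]

#: Fixation times (minutes) of the reference schedule.
FIXATION_TIMES_MIN = (2, 4, 6, 8)

#: Trained (x, y) centers per channel at each fixation time,
#: in the study's normalised units.
REFERENCE_CENTERS: dict[int, dict[str, Point]] = {
    2: {"R": Point(0.91, 0.80), "G": Point(1.16, 0.82), "B": Point(0.72, 0.40)},
    4: {"R": Point(0.93, 0.88), "G": Point(1.09, 0.91), "B": Point(0.76, 0.53)},
    6: {"R": Point(0.68, 1.02), "G": Point(0.77, 1.03), "B": Point(0.56, 0.74)},
    8: {"R": Point(0.54, 1.12), "G": Point(0.58, 1.10), "B": Point(0.43, 0.95)},
}

#: Reported pairwise center distances (d_RG, d_RB, d_GB, sum) at each time.
REFERENCE_DISTANCES: dict[int, dict[str, float]] = {
    2: {"d_RG": 0.25, "d_RB": 0.44, "d_GB": 0.61, "sum": 1.30},
    4: {"d_RG": 0.16, "d_RB": 0.38, "d_GB": 0.50, "sum": 1.04},
    6: {"d_RG": 0.09, "d_RB": 0.30, "d_GB": 0.36, "sum": 0.75},
    8: {"d_RG": 0.04, "d_RB": 0.20, "d_GB": 0.21, "sum": 0.45},
}

#: Fixation time treated as the ideal standard state in the study.
STANDARD_TIME_MIN = 6

#: Decision weight used in the study's evaluation.
REFERENCE_ALPHA = 0.2
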