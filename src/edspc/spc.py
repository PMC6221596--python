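"""Statistical process control primitives.

Rare-events T charts plot the time between successive events.  Because
inter-event times from a process in control are strongly right-skewed
(roughly exponential/Weibull), each gap ``t`` is transformed to
``y = t**(1/3.6)``, which brings the distribution close enough to
symmetric for individuals-chart limits; the chart is read back on the
day scale through the inverse ``t = y**3.6``.  Limits follow the
individuals/moving-range construction: the center line is the mean of
the transformed values and sigma is the mean absolute successive
difference divided by the unbiasing constant d2 = 1.128.

Special-cause variation is detected with the classic Western-Electric /
Nelson style rules:

``outside_3sd``        one point beyond the 3-sigma control limits
``four_of_five_1sd``   >= 4 of 5 consecutive points beyond 1 sigma, same side
``two_of_three_2sd``   >= 2 of 3 consecutive points beyond 2 sigma, same side
``eight_same_side``    >= 8 consecutive points on the same side of center
``six_trending``       >= 6 consecutive points strictly increasing or decreasing

Tie-breaking is deterministic and documented: a point exactly equal to
the center line counts toward neither side, a point exactly on a zone
boundary is inside that zone (all "beyond" comparisons are strict), and
an equal pair of consecutive values resets a trend run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RULES",
    "D2_CONSTANT",
    "TRANSFORM_POWER",
    "ChartLimits",
    "SpecialCauseSignal",
    "InsufficientDataError",
    "event_gaps",
    "t_transform",
    "back_transform",
    "individuals_limits",
    "detect_special_cause",
]

RULES = (
    "outside_3sd",
    "four_of_five_1sd",
    "two_of_three_2sd",
    "eight_same_side",
    "six_trending",
)

#: unbiasing constant for a moving range of 2 (individuals chart)
D2_CONSTANT = 1.128

#: power applied to inter-event gaps before charting: y = t**(1/3.6)
TRANSFORM_POWER = 1.0 / 3.6


class InsufficientDataError(ValueError):
    """Too few points to compute chart limits."""


@dataclass(frozen=True)
class ChartLimits:
    """Center line and sigma on the chart's computation scale.

    ``sigma`` may be a scalar (T chart) or a per-point array (P chart,
    where the binomial sigma varies with subgroup size).
    """

    center: float
    sigma: object  # float or ndarray
    phase: str | None = None

    def zone(self, k: float):
        """(lower, upper) bounds of the ±k-sigma zone."""
        s = np.asarray(self.sigma, dtype=float)
        return self.center - k * s, self.center + k * s

    @property
    def zones(self) -> dict:
        return {k: self.zone(k) for k in (1, 2, 3)}


@dataclass(frozen=True)
class SpecialCauseSignal:
    """One detected special-cause pattern.

    ``point_indices`` are indices into the chart's point sequence; for the
    window rules they are the points beyond the relevant zone within the
    merged run of qualifying windows.  ``direction`` is ``above``/``below``
    for side rules and ``increasing``/``decreasing`` for the trend rule.
    ``reference_phase`` names the phase whose limits triggered the signal.
    """

    rule_id: str
    point_indices: tuple[int, ...]
    direction: str
    reference_phase: str | None = None


def event_gaps(event_times, monitoring_start) -> np.ndarray:
    """Fractional-day gaps between consecutive events.

    The first gap is measured from ``monitoring_start`` to the first
    event; each subsequent gap is the difference between consecutive
    events.  Event times must be strictly increasing and not precede the
    monitoring start; duplicate timestamps are an error (merge or jitter
    them upstream).
    """
    times = np.asarray(event_times, dtype="datetime64[ns]")
    start = np.datetime64(np.datetime64(monitoring_start), "ns")
    if times.size == 0:
        return np.empty(0, dtype=float)
    if np.any(times[:-1] >= times[1:]):
        raise ValueError("event times must be strictly increasing (duplicates must be merged upstream)")
    if times[0] < start:
        raise ValueError("event precedes monitoring start")
    deltas = np.diff(times, prepend=start)
    return deltas / np.timedelta64(1, "D")


def t_transform(gap_days):
    """Power-transform a positive gap (days) onto the charting scale."""
    g = np.asarray(gap_days, dtype=float)
    if np.any(g <= 0):
        raise ValueError("gap must be positive")
    out = g**TRANSFORM_POWER
    return float(out) if np.isscalar(gap_days) else out


def back_transform(y):
    """Inverse of :func:`t_transform`: y**3.6, the gap on the day scale."""
    arr = np.asarray(y, dtype=float) ** (1.0 / TRANSFORM_POWER)
    return float(arr) if np.isscalar(y) else arr


def individuals_limits(values: Sequence[float], phase: str | None = None) -> ChartLimits:
    """Individuals-chart limits: mean center, moving-range sigma.

    sigma = mean(|successive differences|) / 1.128.  Needs at least two
    values; a constant series yields sigma 0 (all zones collapse onto the
    center line).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"need >= 2 values for individuals limits, got {v.size}")
    center = float(v.mean())
    sigma = float(np.abs(np.diff(v)).mean() / D2_CONSTANT)
    return ChartLimits(center=center, sigma=sigma, phase=phase)


# ---------------------------------------------------------------------------
# rule engine


def _merge_windows(starts: np.ndarray, width: int) -> list[tuple[int, int]]:
    """Merge overlapping [s, s+width-1] windows into maximal intervals."""
    merged: list[tuple[int, int]] = []
    for s in np.sort(starts):
        lo, hi = int(s), int(s) + width - 1
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _window_rule_signals(beyond: np.ndarray, width: int, need: int, rule: str,
                         direction: str, ref: str | None, offset: int) -> list[SpecialCauseSignal]:
    n = beyond.size
    if n < width:
        return []
    counts = np.convolve(beyond.astype(int), np.ones(width, dtype=int), mode="valid")
    starts = np.nonzero(counts >= need)[0]
    out = []
    for lo, hi in _merge_windows(starts, width):
        idx = np.nonzero(beyond[lo : hi + 1])[0] + lo
        out.append(SpecialCauseSignal(rule, tuple(int(i) + offset for i in idx), direction, ref))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_special_cause(
    values,
    limits: ChartLimits,
    rules: Sequence[str] = RULES,
    *,
    reference_phase: str | None = None,
    index_offset: int = 0,
) -> list[SpecialCauseSignal]:
    """Apply the selected rules to a sequence of charted values.

    ``values`` and ``limits`` must share a scale (transformed scale for T
    charts, proportion scale for P charts).  Overlapping qualifying
    windows for the same rule and direction are merged into one signal.
    ``index_offset`` shifts reported indices (useful when a phase's points
    are a slice of a longer chart).

    Raises ``ValueError`` for an unknown rule id.
    """
    for r in rules:
        if r not in RULES:
            raise ValueError(f"unknown special-cause rule {r!r}; known rules: {RULES}")
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return []
    sigma = np.broadcast_to(np.asarray(limits.sigma, dtype=float), v.shape)
    dev = v - limits.center
    ref = reference_phase if reference_phase is not None else limits.phase

    signals: list[SpecialCauseSignal] = []
    for direction, sgn in (("above", 1.0), ("below", -1.0)):
        sdev = sgn * dev
        if "outside_3sd" in rules:
            for i in np.nonzero(sdev > 3.0 * sigma)[0]:
                signals.append(
                    SpecialCauseSignal("outside_3sd", (int(i) + index_offset,), direction, ref)
                )
        if "four_of_five_1sd" in rules:
            signals += _window_rule_signals(
                sdev > 1.0 * sigma, 5, 4, "four_of_five_1sd", direction, ref, index_offset
            )
        if "two_of_three_2sd" in rules:
            signals += _window_rule_signals(
                sdev > 2.0 * sigma, 3, 2, "two_of_three_2sd", direction, ref, index_offset
            )
        if "eight_same_side" in rules:
            for lo, hi in _runs(sdev > 0):
                if hi - lo + 1 >= 8:
                    signals.append(
                        SpecialCauseSignal(
                            "eight_same_side",
                            tuple(range(lo + index_offset, hi + 1 + index_offset)),
                            direction,
                            ref,
                        )
                    )
    if "six_trending" in rules and n >= 2:
        diffs = np.diff(v)
        for direction, mask in (("increasing", diffs > 0), ("decreasing", diffs < 0)):
            for lo, hi in _runs(mask):
                npts = hi - lo + 2  # a run of k strict steps spans k+1 points
                if npts >= 6:
                    signals.append(
                        SpecialCauseSignal(
                            "six_trending",
                            tuple(range(lo + index_offset, hi + 2 + index_offset)),
                            direction,
                            ref,
                        )
                    )
    order = {r: i for i, r in enumerate(RULES)}
    signals.sort(key=lambda s: (order[s.rule_id], s.point_indices[0], s.direction))
    return signals
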