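"""Quality-improvement outcome, process, balancing and financial measures.

* BCCR — blood culture contamination rate: contaminant cultures / all
  included peripheral cultures ordered in a phase.
* BCOR — blood culture ordering rate: included cultures ordered / all ED
  visits in a phase.
* Balancing measure — among patients discharged without a culture who
  returned within 48 hours and had a culture on the return visit, the
  proportion whose return culture grew a pathogen (possible missed
  bacteremia), compared before vs after the ordering-guideline phase
  with a Wald two-proportion 95% CI.
* Financial measure — expected contaminants in the final phase under
  baseline ordering and contamination rates, minus observed
  contaminants, priced at a per-contaminant charge (default $3,166 in
  2017 dollars).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phases import PhasePlan

__all__ = [
    "UndefinedRateError",
    "RateSummary",
    "TwoPropResult",
    "BalancingResult",
    "FinancialResult",
    "bccr",
    "bcor",
    "relative_decrease",
    "two_prop_diff_ci",
    "balancing_measure",
    "financial_savings",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over an empty denominator."""


@dataclass(frozen=True)
class RateSummary:
    """A per-phase count-based proportion."""

    phase: str
    numerator: int
    denominator: int
    rate: float

    @property
    def pct(self) -> float:
        """The rate as a percentage rounded to 2 decimals (printed precision)."""
        return round(100 * self.rate, 2)


@dataclass(frozen=True)
class TwoPropResult:
    """Wald difference-of-proportions comparison, p1 - p2."""

    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    diff: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


@dataclass(frozen=True)
class BalancingResult:
    """48-hour return-visit missed-bacteremia comparison, pre vs post.

    ``comparison`` is None when either period has a zero denominator —
    the comparison is then reported as unavailable, not silently zero.
    """

    x_pre: int
    n_pre: int
    x_post: int
    n_post: int
    window_hours: float
    split_date: pd.Timestamp
    comparison: TwoPropResult | None

    @property
    def available(self) -> bool:
        return self.comparison is not None


@dataclass(frozen=True)
class FinancialResult:
    """Expected-vs-actual contaminant charge savings."""

    n_patients: int
    baseline_bcor: float
    baseline_bccr: float
    expected_contaminants: float
    actual_contaminants: int
    averted: float
    charge_per_contaminant: float
    savings: float

    @property
    def expected_rounded(self) -> int:
        return int(round(self.expected_contaminants))


def _phase_mask(ts: pd.Series, plan: PhasePlan, phase: str) -> pd.Series:
    p = plan[phase]
    t = pd.to_datetime(ts)
    return (t >= p.start_ts) & (t < p.end_exclusive_ts)


def bccr(cultures: pd.DataFrame, plan: PhasePlan, phase: str) -> RateSummary:
    """Blood culture contamination rate for one phase.

    ``cultures`` is a classified table; exclusion-flagged records are
    dropped here if still present, so the rate is always over the
    analysis set.  Denominator: included cultures ordered in the phase;
    numerator: those with a contaminant outcome.
    """
    df = cultures
    if "included" in df.columns:
        df = df.loc[df["included"]]
    in_phase = df.loc[_phase_mask(df["ordered_at"], plan, phase)]
    denom = len(in_phase)
    if denom == 0:
        raise UndefinedRateError(f"no included cultures in phase {phase!r}")
    num = int((in_phase["outcome"] == "contaminant").sum())
    return RateSummary(phase=phase, numerator=num, denominator=denom, rate=num / denom)


def bcor(visits: pd.DataFrame, cultures: pd.DataFrame, plan: PhasePlan, phase: str) -> RateSummary:
    """Blood culture ordering rate for one phase.

    Numerator: included cultures ordered in the phase; denominator: ED
    visits arriving in the phase.
    """
    df = cultures
    if "included" in df.columns:
        df = df.loc[df["included"]]
    num = int(_phase_mask(df["ordered_at"], plan, phase).sum())
    denom = int(_phase_mask(visits["arrival"], plan, phase).sum())
    if denom == 0:
        raise UndefinedRateError(f"no visits in phase {phase!r}")
    return RateSummary(phase=phase, numerator=num, denominator=denom, rate=num / denom)


def relative_decrease(baseline_rate: float, current_rate: float) -> float:
    """Percent decrease from baseline: 100·(baseline − current)/baseline.

    Returned raw; reports print it to the nearest integer percent.
    """
    if baseline_rate <= 0:
        raise UndefinedRateError("relative decrease undefined for zero baseline rate")
    return 100.0 * (baseline_rate - current_rate) / baseline_rate


def two_prop_diff_ci(x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05) -> TwoPropResult:
    """Wald 95% CI for p1 − p2, no continuity correction.

    diff ± z·sqrt(p1(1−p1)/n1 + p2(1−p2)/n2) with z the standard-normal
    1−α/2 quantile.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within their denominators")
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    z = float(stats.norm.ppf(1 - alpha / 2))
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2))
    return TwoPropResult(
        x1=x1, n1=n1, x2=x2, n2=n2, p1=p1, p2=p2,
        diff=diff, ci_low=diff - z * se, ci_high=diff + z * se, alpha=alpha,
    )


def find_return_pairs(
    visits: pd.DataFrame,
    cultures: pd.DataFrame,
    window_hours: float = 48.0,
) -> pd.DataFrame:
    """Qualifying 48-hour return-visit pairs.

    A pair (visit 1, visit 2) of the same patient qualifies when visit 1
    ended in discharge with no blood culture, visit 2 began no more than
    ``window_hours`` after visit 1's departure (and not before it), and
    visit 2 had a blood culture.  A patient may contribute several pairs;
    each pair counts once.

    Returns a frame with ``patient_id, visit1_id, visit2_id,
    visit2_arrival, pathogenic`` (whether any visit-2 culture grew a
    pathogen).
    """
    window = pd.Timedelta(hours=window_hours)
    cultured = set(cultures["visit_id"])
    pathogenic = (
        set(cultures.loc[cultures["outcome"] == "pathogen", "visit_id"])
        if "outcome" in cultures.columns
        else set()
    )
    v = visits.sort_values(["patient_id", "arrival"], kind="mergesort")
    multi = v["patient_id"].duplicated(keep=False)
    rows = []
    for _, grp in v.loc[multi].groupby("patient_id", sort=False):
        recs = grp.to_dict("records")
        for i, v1 in enumerate(recs):
            if v1["disposition"] != "discharged" or v1["visit_id"] in cultured:
                continue
            for v2 in recs[i + 1 :]:
                delta = v2["arrival"] - v1["departure"]
                if delta > window:
                    break
                if delta < pd.Timedelta(0) or v2["visit_id"] not in cultured:
                    continue
                rows.append(
                    {
                        "patient_id": v1["patient_id"],
                        "visit1_id": v1["visit_id"],
                        "visit2_id": v2["visit_id"],
                        "visit2_arrival": v2["arrival"],
                        "pathogenic": v2["visit_id"] in pathogenic,
                    }
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "visit1_id", "visit2_id", "visit2_arrival", "pathogenic"]
    )


def balancing_measure(
    visits: pd.DataFrame,
    cultures: pd.DataFrame,
    split_date,
    window_hours: float = 48.0,
    alpha: float = 0.05,
) -> BalancingResult:
    """Missed-bacteremia balancing measure, pre vs post ``split_date``.

    Pairs (see :func:`find_return_pairs`) are assigned to the pre or
    post period by the return visit's arrival; the numerator counts
    pairs whose return culture was pathogenic.  Uses *all* classified
    cultures (exclusion flags do not apply: a missed bacteremia is a
    harm regardless).  When either period has no qualifying pairs the
    comparison is unavailable (``comparison is None``).
    """
    split = pd.Timestamp(split_date)
    pairs = find_return_pairs(visits, cultures, window_hours)
    if len(pairs):
        post = pairs["visit2_arrival"] >= split
        n_pre, n_post = int((~post).sum()), int(post.sum())
        x_pre = int(pairs.loc[~post, "pathogenic"].sum())
        x_post = int(pairs.loc[post, "pathogenic"].sum())
    else:
        n_pre = n_post = x_pre = x_post = 0
    comparison = (
        two_prop_diff_ci(x_pre, n_pre, x_post, n_post, alpha) if n_pre > 0 and n_post > 0 else None
    )
    return BalancingResult(
        x_pre=x_pre, n_pre=n_pre, x_post=x_post, n_post=n_post,
        window_hours=window_hours, split_date=split, comparison=comparison,
    )


def financial_savings(
    n_patients: int,
    baseline_bcor: float,
    baseline_bccr: float,
    actual_contaminants: int,
    charge_per_contaminant: float = 3166.0,
    expected_contaminants: float | None = None,
) -> FinancialResult:
    """Charge savings from contaminants averted in the final phase.

    Expected contaminants = final-phase patient count × baseline BCOR ×
    baseline BCCR, unless an explicit ``expected_contaminants`` count is
    supplied; averted = expected − actual; savings = averted × charge.
    The charge is an input already expressed in target-year dollars.
    """
    if n_patients < 0 or actual_contaminants < 0 or charge_per_contaminant < 0:
        raise ValueError("counts and charge must be nonnegative")
    if not (0 < baseline_bcor < 1 and 0 < baseline_bccr < 1):
        raise ValueError("baseline rates must lie in (0, 1)")
    expected = (
        float(expected_contaminants)
        if expected_contaminants is not None
        else n_patients * baseline_bcor * baseline_bccr
    )
    averted = expected - actual_contaminants
    return FinancialResult(
        n_patients=int(n_patients),
        baseline_bcor=baseline_bcor,
        baseline_bccr=baseline_bccr,
        expected_contaminants=expected,
        actual_contaminants=int(actual_contaminants),
        averted=averted,
        charge_per_contaminant=charge_per_contaminant,
        savings=averted * charge_per_contaminant,
    )
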