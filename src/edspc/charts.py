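"""T and P control charts over a phased study plan.

:class:`TChart` is the rare-events chart: one point per contaminant
event, plotting the (power-transformed) days since the previous event.
:class:`PChart` is the attribute chart of the per-period proportion of
ED visits with a peripheral blood culture ordered, with binomial limits
that widen as the subgroup shrinks.

Both are scikit-learn style estimators: construct with parameters, call
``fit``, read fitted ``points_`` / ``limits_`` / ``signals_`` attributes.
Per-phase *display* limits are always computed from that phase's own
points; under the default ``recalc_policy="freeze_prior"`` special-cause
*detection* in each post-baseline phase is evaluated against the frozen
limits of the phase before it, which is how an interrupted time series
asks "did this cycle shift the process relative to where it was?".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .phases import PhasePlan, default_plan
from .spc import (
    RULES,
    ChartLimits,
    InsufficientDataError,
    SpecialCauseSignal,
    back_transform,
    detect_special_cause,
    event_gaps,
    individuals_limits,
    t_transform,
)

__all__ = ["TChart", "PChart", "build_t_chart", "build_p_chart", "subgroup_counts"]

logger = logging.getLogger(__name__)

RECALC_POLICIES = ("freeze_prior", "recompute_only")


def _check_policy(policy: str) -> None:
    if policy not in RECALC_POLICIES:
        raise ValueError(f"recalc_policy must be one of {RECALC_POLICIES}, got {policy!r}")


class TChart(BaseEstimator):
    """Rare-events chart of time between contaminant cultures.

    Parameters
    ----------
    phase_plan : PhasePlan, optional
        Defaults to the four-phase baseline + PDSA plan.
    recalc_policy : {"freeze_prior", "recompute_only"}
        ``freeze_prior`` (default) detects special cause in each
        post-baseline phase against the previous phase's limits;
        ``recompute_only`` detects every phase against its own limits.
    rules : sequence of rule ids
        Special-cause rules to apply (default: all five).
    first_gap : {"from_start", "drop"}
        Whether the first event's gap is measured from the monitoring
        start (default) or the first event only anchors the clock.
    monitoring_start : timestamp, optional
        Defaults to the plan's first day.

    Attributes
    ----------
    points_ : DataFrame with ``event_time, gap_days, y, phase``.
    limits_ : dict phase -> ChartLimits (transformed scale) or None when a
        phase has fewer than two points.
    center_days_ : dict phase -> back-transformed center line ("1 event
        every k days") or None.
    signals_ : list of SpecialCauseSignal with indices into ``points_``.
    """

    def __init__(
        self,
        phase_plan: PhasePlan | None = None,
        recalc_policy: str = "freeze_prior",
        rules=RULES,
        first_gap: str = "from_start",
        monitoring_start=None,
    ):
        self.phase_plan = phase_plan
        self.recalc_policy = recalc_policy
        self.rules = rules
        self.first_gap = first_gap
        self.monitoring_start = monitoring_start

    def fit(self, X, y=None):
        """Fit the chart to event times.

        ``X`` may be a DataFrame with an ``ordered_at`` column or any
        array-like of timestamps, strictly increasing, all inside the
        phase plan's overall span.
        """
        _check_policy(self.recalc_policy)
        if self.first_gap not in ("from_start", "drop"):
            raise ValueError(f"first_gap must be 'from_start' or 'drop', got {self.first_gap!r}")
        plan = self.phase_plan or default_plan()
        times = X["ordered_at"] if isinstance(X, pd.DataFrame) else X
        times = pd.to_datetime(pd.Series(np.asarray(times))).to_numpy(dtype="datetime64[ns]")
        start = pd.Timestamp(self.monitoring_start) if self.monitoring_start is not None else plan.start_ts
        phases = plan.phase_of(times)
        if any(p is None for p in phases):
            raise ValueError("event(s) fall outside the phase plan's span")

        gaps = event_gaps(times, start)
        if self.first_gap == "drop" and gaps.size:
            times, gaps, phases = times[1:], gaps[1:], phases[1:]
        yvals = t_transform(gaps) if gaps.size else np.empty(0)

        self.plan_ = plan
        self.points_ = pd.DataFrame(
            {"event_time": times, "gap_days": gaps, "y": yvals, "phase": phases}
        )

        self.limits_: dict[str, ChartLimits | None] = {}
        self.center_days_: dict[str, float | None] = {}
        for name in plan.names:
            vals = self.points_.loc[self.points_["phase"] == name, "y"].to_numpy()
            if vals.size >= 2:
                lim = individuals_limits(vals, phase=name)
                self.limits_[name] = lim
                self.center_days_[name] = back_transform(lim.center)
            else:
                self.limits_[name] = None
                self.center_days_[name] = None

        self.signals_ = self._detect()
        return self

    def _reference_limits(self, phase: str) -> ChartLimits | None:
        """Limits a phase is judged against under the active policy."""
        i = self.plan_.index(phase)
        if self.recalc_policy == "recompute_only" or i == 0:
            return self.limits_[phase]
        for j in range(i - 1, -1, -1):  # nearest earlier phase with usable limits
            lim = self.limits_[self.plan_.names[j]]
            if lim is not None:
                return lim
        return self.limits_[phase]

    def _detect(self) -> list[SpecialCauseSignal]:
        signals: list[SpecialCauseSignal] = []
        phase_col = self.points_["phase"].to_numpy()
        for name in self.plan_.names:
            idx = np.nonzero(phase_col == name)[0]
            if idx.size == 0:
                continue
            lim = self._reference_limits(name)
            if lim is None:
                logger.info("phase %s: no usable limits, detection skipped", name)
                continue
            signals += detect_special_cause(
                self.points_["y"].to_numpy()[idx],
                lim,
                self.rules,
                reference_phase=lim.phase,
                index_offset=int(idx[0]),
            )
        return signals

    def to_frame(self) -> pd.DataFrame:
        """Per-point table with display limits (both scales) and signal flags."""
        df = self.points_.copy()
        for col in ("center_y", "lcl_y", "ucl_y"):
            df[col] = np.nan
        for name, lim in self.limits_.items():
            if lim is None:
                continue
            m = df["phase"] == name
            lo, hi = lim.zone(3)
            df.loc[m, "center_y"] = lim.center
            df.loc[m, "lcl_y"] = max(float(lo), 0.0)
            df.loc[m, "ucl_y"] = float(hi)
        df["center_days"] = back_transform(df["center_y"].to_numpy())
        df["lcl_days"] = back_transform(np.clip(df["lcl_y"].to_numpy(), 0.0, None))
        df["ucl_days"] = back_transform(df["ucl_y"].to_numpy())
        df["signals"] = _signal_column(len(df), self.signals_)
        return df

    def plot(self, ax=None):
        """Render the chart on the day scale (points, center line, limits)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        df = self.to_frame()
        x = np.arange(len(df))
        ax.plot(x, df["gap_days"], "o-", ms=3, lw=0.8, color="tab:blue", label="days between events")
        ax.step(x, df["center_days"], where="mid", color="tab:green", label="center line")
        ax.step(x, df["ucl_days"], where="mid", color="tab:red", lw=0.8, label="UCL")
        flagged = df.index[df["signals"] != ""]
        ax.plot(flagged, df.loc[flagged, "gap_days"], "o", ms=6, mfc="none", mec="tab:red")
        for name in self.plan_.names:
            m = np.nonzero((df["phase"] == name).to_numpy())[0]
            if m.size:
                ax.axvline(m[0] - 0.5, color="gray", lw=0.6, ls="--")
                ax.text(m[0], ax.get_ylim()[1], name, fontsize=8, va="bottom")
        ax.set_xlabel("contaminant event #")
        ax.set_ylabel("days since prior contaminant")
        ax.legend(loc="upper left", fontsize=8)
        return ax


def subgroup_counts(
    visits: pd.DataFrame,
    cultures: pd.DataFrame,
    plan: PhasePlan | None = None,
    period: str = "monthly",
) -> pd.DataFrame:
    """Aggregate visits/cultures into P-chart subgroups.

    One row per (phase, calendar period): ``denominator`` counts ED
    visits arriving in the period, ``numerator`` counts those visits with
    at least one included culture (the charted proportion is "patients
    with a culture ordered", so the numerator can never exceed the
    denominator even for multi-culture visits).  Periods with zero visits
    are omitted and logged.  Visits outside the plan are ignored.
    """
    if period not in ("monthly", "weekly"):
        raise ValueError(f"period must be 'monthly' or 'weekly', got {period!r}")
    plan = plan or default_plan()
    freq = "M" if period == "monthly" else "W"

    v = visits.copy()
    v["phase"] = plan.phase_of(v["arrival"])
    n_outside = int(v["phase"].isna().sum()) if v["phase"].dtype != object else sum(
        p is None for p in v["phase"]
    )
    if n_outside:
        logger.info("%d visit(s) outside the phase plan omitted from the P chart", n_outside)
    v = v.loc[[p is not None for p in v["phase"]]]
    v["period_start"] = pd.to_datetime(v["arrival"]).dt.to_period(freq).dt.start_time

    cultured = cultures.loc[cultures["included"], "visit_id"].unique() if "included" in cultures else (
        cultures["visit_id"].unique()
    )
    v["has_culture"] = v["visit_id"].isin(cultured)

    grouped = (
        v.groupby(["phase", "period_start"], sort=False)
        .agg(numerator=("has_culture", "sum"), denominator=("visit_id", "size"))
        .reset_index()
    )
    order = {name: i for i, name in enumerate(plan.names)}
    grouped["__k"] = grouped["phase"].map(order)
    grouped = grouped.sort_values(["period_start", "__k"], kind="mergesort").drop(columns="__k")
    grouped["numerator"] = grouped["numerator"].astype(int)
    return grouped.reset_index(drop=True)


class PChart(BaseEstimator):
    """Proportion chart of culture ordering per calendar period.

    ``fit`` takes a subgroup table (``period_start, numerator,
    denominator`` and optionally ``phase``; see :func:`subgroup_counts`).
    The phase center line is the pooled proportion Σx/Σn over the phase;
    each point's sigma is sqrt(p̄(1-p̄)/nᵢ), so limits widen for small
    subgroups.  Default special-cause rule set is the single
    ``outside_3sd`` rule; under ``freeze_prior`` post-baseline phases are
    judged against the prior phase's pooled center.

    Attributes
    ----------
    points_ : DataFrame with ``period_start, phase, numerator,
        denominator, p_hat``.
    centers_ : dict phase -> pooled proportion (None for empty phases).
    limits_ : dict phase -> ChartLimits with per-point sigma array.
    signals_ : list of SpecialCauseSignal.
    """

    def __init__(
        self,
        phase_plan: PhasePlan | None = None,
        recalc_policy: str = "freeze_prior",
        rules=("outside_3sd",),
    ):
        self.phase_plan = phase_plan
        self.recalc_policy = recalc_policy
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None):
        _check_policy(self.recalc_policy)
        plan = self.phase_plan or default_plan()
        df = X.copy()
        for col in ("period_start", "numerator", "denominator"):
            if col not in df.columns:
                raise ValueError(f"subgroup table missing column {col!r}")
        if "phase" not in df.columns:
            df["phase"] = plan.phase_of(pd.to_datetime(df["period_start"]))
            df = df.loc[[p is not None for p in df["phase"]]]
        if (df["denominator"] <= 0).any():
            raise ValueError("subgroup denominator must be positive")
        if (df["numerator"] > df["denominator"]).any():
            raise ValueError("subgroup numerator exceeds denominator")
        df = df.reset_index(drop=True)
        df["p_hat"] = df["numerator"] / df["denominator"]

        self.plan_ = plan
        self.centers_: dict[str, float | None] = {}
        self.limits_: dict[str, ChartLimits | None] = {}
        for name in plan.names:
            m = df["phase"] == name
            if not m.any():
                self.centers_[name] = None
                self.limits_[name] = None
                continue
            pbar = float(df.loc[m, "numerator"].sum() / df.loc[m, "denominator"].sum())
            self.centers_[name] = pbar
            sig = np.sqrt(pbar * (1 - pbar) / df.loc[m, "denominator"].to_numpy(dtype=float))
            self.limits_[name] = ChartLimits(center=pbar, sigma=sig, phase=name)
        self.points_ = df

        self.signals_ = self._detect()
        return self

    def _detect(self) -> list[SpecialCauseSignal]:
        signals: list[SpecialCauseSignal] = []
        phase_col = self.points_["phase"].to_numpy()
        for name in self.plan_.names:
            idx = np.nonzero(phase_col == name)[0]
            if idx.size == 0:
                continue
            ref_name = name
            if self.recalc_policy == "freeze_prior":
                i = self.plan_.index(name)
                for j in range(i - 1, -1, -1):
                    if self.centers_[self.plan_.names[j]] is not None:
                        ref_name = self.plan_.names[j]
                        break
            center = self.centers_[ref_name]
            if center is None:
                logger.info("phase %s: no usable center, detection skipped", name)
                continue
            n_i = self.points_["denominator"].to_numpy(dtype=float)[idx]
            lim = ChartLimits(center=center, sigma=np.sqrt(center * (1 - center) / n_i), phase=ref_name)
            signals += detect_special_cause(
                self.points_["p_hat"].to_numpy()[idx],
                lim,
                self.rules,
                reference_phase=ref_name,
                index_offset=int(idx[0]),
            )
        return signals

    def to_frame(self) -> pd.DataFrame:
        """Per-point table with clipped display limits and signal flags."""
        df = self.points_.copy()
        center = np.full(len(df), np.nan)
        lcl = np.full(len(df), np.nan)
        ucl = np.full(len(df), np.nan)
        for name, lim in self.limits_.items():
            if lim is None:
                continue
            m = (df["phase"] == name).to_numpy()
            lo, hi = lim.zone(3)
            center[m] = lim.center
            lcl[m] = np.clip(lo, 0.0, 1.0)
            ucl[m] = np.clip(hi, 0.0, 1.0)
        df["center"] = center
        df["lcl"] = lcl
        df["ucl"] = ucl
        df["signals"] = _signal_column(len(df), self.signals_)
        return df

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        df = self.to_frame()
        x = pd.to_datetime(df["period_start"])
        ax.plot(x, 100 * df["p_hat"], "o-", ms=3, lw=0.8, color="tab:blue", label="% visits with culture")
        ax.step(x, 100 * df["center"], where="post", color="tab:green", label="center line")
        ax.step(x, 100 * df["ucl"], where="post", color="tab:red", lw=0.8, label="UCL/LCL")
        ax.step(x, 100 * df["lcl"], where="post", color="tab:red", lw=0.8)
        flagged = df["signals"] != ""
        ax.plot(x[flagged], 100 * df.loc[flagged, "p_hat"], "o", ms=6, mfc="none", mec="tab:red")
        ax.set_ylabel("% of ED visits with a blood culture")
        ax.legend(loc="upper right", fontsize=8)
        return ax


def _signal_column(n: int, signals: list[SpecialCauseSignal]) -> pd.Series:
    flags: list[set[str]] = [set() for _ in range(n)]
    for s in signals:
        for i in s.point_indices:
            flags[i].add(s.rule_id)
    return pd.Series(["|".join(sorted(f)) for f in flags])


def build_t_chart(events, plan: PhasePlan | None = None, recalc_policy: str = "freeze_prior", **kw) -> TChart:
    """Fit a :class:`TChart` to contaminant events.

    ``events`` may be a classified culture table (rows are filtered to
    included contaminants if ``outcome``/``included`` columns are
    present) or a plain sequence of event timestamps.
    """
    if isinstance(events, pd.DataFrame):
        df = events
        if "outcome" in df.columns:
            df = df.loc[df["outcome"] == "contaminant"]
        if "included" in df.columns:
            df = df.loc[df["included"]]
        events = df["ordered_at"].sort_values(kind="mergesort")
    return TChart(phase_plan=plan, recalc_policy=recalc_policy, **kw).fit(events)


def build_p_chart(
    visits: pd.DataFrame,
    cultures: pd.DataFrame,
    plan: PhasePlan | None = None,
    period: str = "monthly",
    recalc_policy: str = "freeze_prior",
    **kw,
) -> PChart:
    """Aggregate to subgroups and fit a :class:`PChart`."""
    counts = subgroup_counts(visits, cultures, plan, period)
    return PChart(phase_plan=plan, recalc_policy=recalc_policy, **kw).fit(counts)
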