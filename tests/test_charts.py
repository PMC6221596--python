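"""T-chart and P-chart construction, phase limits and cross-phase detection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gamma

import edspc
from edspc import PChart, Phase, PhasePlan, TChart, default_plan, subgroup_counts
from edspc.charts import build_p_chart, build_t_chart


def _exp_event_times(rng, mean_gap, n, start="2014-07-01"):
    gaps = rng.exponential(mean_gap, n)
    return pd.Timestamp(start) + pd.to_timedelta(np.cumsum(gaps), unit="D")


class TestTChart:
    def test_all_events_in_baseline_only(self):
        rng = np.random.default_rng(5)
        times = _exp_event_times(rng, 2.0, 100)
        chart = TChart().fit(times)
        assert chart.limits_["baseline"] is not None
        assert all(chart.limits_[p] is None for p in ("pdsa1", "pdsa2", "pdsa3"))
        # with no post-baseline points, every signal references baseline limits
        assert all(s.reference_phase == "baseline" for s in chart.signals_)

    def test_back_transformed_center_matches_closed_form(self):
        # for exponential gaps of mean m, E[t^(1/3.6)] = m^(1/3.6)·Γ(1+1/3.6),
        # so the back-transformed center line converges to m·Γ(1+1/3.6)^3.6
        rng = np.random.default_rng(42)
        m = 3.0
        times = _exp_event_times(rng, m, 10_000)
        plan = PhasePlan([Phase("all", "2014-07-01", "2200-01-01")])
        chart = TChart(phase_plan=plan).fit(times)
        closed_form = m * gamma(1 + 1 / 3.6) ** 3.6
        assert chart.center_days_["all"] == pytest.approx(closed_form, rel=0.04)

    def test_planted_rate_drop_produces_above_signal(self):
        stream = edspc.planted_changepoint_stream(
            edspc.GeneratorConfig(seed=1), shift=1 / 3, boundary="pdsa3"
        )
        classified = edspc.classify_cultures(stream.cultures)
        chart = build_t_chart(edspc.analysis_set(classified))
        pdsa3 = chart.points_["phase"] == "pdsa3"
        idx = set(np.nonzero(pdsa3.to_numpy())[0])
        hits = [
            s
            for s in chart.signals_
            if s.direction == "above" and set(s.point_indices) & idx
        ]
        assert hits, "expected an above-center signal after a 3x gap lengthening"

    def test_phase_with_single_event_has_no_limits_but_keeps_point(self):
        plan = PhasePlan([Phase("a", "2020-01-01", "2020-03-31"), Phase("b", "2020-04-01", "2020-06-30")])
        times = pd.to_datetime(["2020-01-10", "2020-01-20", "2020-02-01", "2020-05-01"])
        chart = TChart(phase_plan=plan).fit(times)
        assert chart.limits_["b"] is None
        assert (chart.points_["phase"] == "b").sum() == 1
        # freeze_prior still judges the lone b point against a's limits
        assert all(s.reference_phase == "a" for s in chart.signals_)

    def test_event_outside_plan_rejected(self):
        with pytest.raises(ValueError, match="outside the phase plan"):
            TChart().fit(pd.to_datetime(["2019-01-01"]))

    def test_first_gap_conventions(self):
        times = pd.to_datetime(["2014-07-03", "2014-07-08"])
        kept = TChart(first_gap="from_start").fit(times)
        assert kept.points_["gap_days"].tolist() == pytest.approx([2.0, 5.0])
        dropped = TChart(first_gap="drop").fit(times)
        assert dropped.points_["gap_days"].tolist() == pytest.approx([5.0])

    def test_recompute_only_references_own_phase(self):
        rng = np.random.default_rng(8)
        times = _exp_event_times(rng, 2.5, 400)
        chart = TChart(recalc_policy="recompute_only").fit(times)
        for s in chart.signals_:
            phases = set(chart.points_["phase"].iloc[list(s.point_indices)])
            assert phases == {s.reference_phase}

    def test_false_alarm_rate_of_3sd_rule_under_stationarity(self):
        # a stationary exponential process should rarely breach the 3-sigma
        # limits on the transformed scale (guards the transform + limits math)
        rng = np.random.default_rng(99)
        times = _exp_event_times(rng, 1.0, 3000)
        plan = PhasePlan([Phase("all", "2014-07-01", "2200-01-01")])
        chart = TChart(phase_plan=plan, rules=("outside_3sd",)).fit(times)
        flagged = {i for s in chart.signals_ for i in s.point_indices}
        assert len(flagged) / 3000 < 0.02

    def test_to_frame_back_transform_consistency(self):
        rng = np.random.default_rng(12)
        chart = TChart().fit(_exp_event_times(rng, 2.0, 150))
        df = chart.to_frame()
        got = df["center_days"].dropna().unique()
        assert got == pytest.approx([chart.center_days_["baseline"]])
        assert (df["lcl_days"].dropna() >= 0).all()


class TestPChart:
    def test_single_period_proportion(self):
        counts = pd.DataFrame(
            {"period_start": [pd.Timestamp("2014-07-01")], "numerator": [48], "denominator": [1000]}
        )
        chart = PChart().fit(counts)
        assert chart.points_["p_hat"].item() == pytest.approx(0.048)
        assert chart.centers_["baseline"] == pytest.approx(0.048)

    def test_limits_widen_as_subgroup_shrinks(self):
        counts = pd.DataFrame(
            {
                "period_start": pd.to_datetime(["2014-07-01", "2014-08-01"]),
                "numerator": [5, 500],
                "denominator": [100, 10_000],
            }
        )
        chart = PChart().fit(counts)
        frame = chart.to_frame()
        width = frame["ucl"] - frame["lcl"]
        assert width.iloc[0] > width.iloc[1]

    def test_phase_center_is_pooled_proportion(self):
        rng = np.random.default_rng(3)
        months = pd.date_range("2014-07-01", periods=12, freq="MS")
        den = rng.integers(500, 1500, 12)
        num = rng.binomial(den, 0.05)
        chart = PChart().fit(
            pd.DataFrame({"period_start": months, "numerator": num, "denominator": den})
        )
        assert chart.centers_["baseline"] == pytest.approx(num.sum() / den.sum())

    def test_phase_center_invariant_to_period_granularity(self, small_stream):
        classified = edspc.classify_cultures(small_stream.cultures)
        monthly = build_p_chart(small_stream.visits, classified, period="monthly")
        weekly = build_p_chart(small_stream.visits, classified, period="weekly")
        for phase in default_plan().names:
            assert monthly.centers_[phase] == pytest.approx(weekly.centers_[phase])

    def test_numerator_counts_visits_not_cultures(self):
        # two cultures on one visit must not push the proportion above 1
        visits = pd.DataFrame(
            {
                "visit_id": ["V1"],
                "patient_id": ["P1"],
                "arrival": [pd.Timestamp("2014-07-05 10:00")],
                "departure": [pd.Timestamp("2014-07-05 14:00")],
                "disposition": ["discharged"],
            }
        )
        cultures = pd.DataFrame(
            {
                "culture_id": ["C1", "C2"],
                "visit_id": ["V1", "V1"],
                "patient_id": ["P1", "P1"],
                "ordered_at": pd.to_datetime(["2014-07-05 11:00", "2014-07-05 12:00"]),
                "result": ["no_growth", "no_growth"],
                "organism": ["", ""],
                "exclusion_flags": ["", ""],
            }
        )
        counts = subgroup_counts(visits, edspc.classify_cultures(cultures))
        assert counts["numerator"].item() == 1 and counts["denominator"].item() == 1

    def test_detection_against_prior_phase_center(self, small_stream):
        classified = edspc.classify_cultures(small_stream.cultures)
        chart = build_p_chart(small_stream.visits, classified)
        for s in chart.signals_:
            phase = chart.points_["phase"].iloc[s.point_indices[0]]
            if phase != "baseline":
                assert s.reference_phase == chart.plan_.prior(phase) or s.reference_phase != phase

    def test_subgroup_counts_match_brute_force(self, small_stream):
        classified = edspc.classify_cultures(small_stream.cultures)
        counts = subgroup_counts(small_stream.visits, classified, period="monthly")
        # brute force one arbitrary month
        month = counts.iloc[5]
        lo = month["period_start"]
        hi = lo + pd.offsets.MonthBegin(1)
        in_month = small_stream.visits[
            (small_stream.visits["arrival"] >= lo) & (small_stream.visits["arrival"] < hi)
        ]
        assert month["denominator"] == len(in_month)
        cultured = set(classified.loc[classified["included"], "visit_id"])
        assert month["numerator"] == sum(v in cultured for v in in_month["visit_id"])
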