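"""End-to-end analysis: classify → charts → measures → JSON report.

:func:`analyze` runs the whole interrupted time-series analysis on a
validated visit/culture pair and returns a plain, JSON-serialisable
dictionary.  The report is deterministic: identical inputs and options
produce byte-identical ``report.json`` (wall-clock time only ever
appears in the run manifest, never in the report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .charts import PChart, TChart, build_p_chart, build_t_chart
from .measures import (
    UndefinedRateError,
    balancing_measure,
    bccr,
    bcor,
    financial_savings,
    relative_decrease,
)
from .organisms import OrganismTable, analysis_set, classify_cultures
from .phases import PhasePlan, default_plan

__all__ = ["analyze", "rates_frame", "write_manifest", "sha256_file"]


def _signals_json(signals) -> list[dict]:
    return [
        {
            "rule": s.rule_id,
            "direction": s.direction,
            "point_indices": list(s.point_indices),
            "reference_phase": s.reference_phase,
        }
        for s in signals
    ]


def analyze(
    visits: pd.DataFrame,
    cultures: pd.DataFrame,
    *,
    organism_table: OrganismTable | None = None,
    plan: PhasePlan | None = None,
    period: str = "monthly",
    recalc_policy: str = "freeze_prior",
    window_hours: float = 48.0,
    charge_per_contaminant: float = 3166.0,
) -> dict:
    """Run the full analysis and return the report dictionary.

    Also returns the fitted chart objects under the ``"_charts"`` key of
    the second element; see the CLI for how the report is serialised.
    """
    plan = plan or default_plan()
    classified = classify_cultures(cultures, organism_table)
    included = analysis_set(classified)
    if included.empty:
        raise ValueError(
            "analysis set is empty: every culture carries an exclusion flag or no cultures were loaded"
        )

    rates: dict[str, dict] = {}
    for name in plan.names:
        entry: dict = {}
        for measure, fn in (("bccr", lambda n: bccr(included, plan, n)),
                            ("bcor", lambda n: bcor(visits, included, plan, n))):
            try:
                r = fn(name)
                entry[measure] = {
                    "numerator": r.numerator,
                    "denominator": r.denominator,
                    "rate": r.rate,
                    "pct": r.pct,
                }
            except UndefinedRateError:
                entry[measure] = None
        rates[name] = entry

    first, last = plan.names[0], plan.names[-1]
    rel: dict[str, dict] = {}
    for measure in ("bccr", "bcor"):
        base = rates[first][measure]
        cur = rates[last][measure]
        if base and cur and base["rate"] > 0:
            raw = relative_decrease(base["rate"], cur["rate"])
            rel[measure] = {"pct": raw, "pct_rounded": int(round(raw))}
        else:
            rel[measure] = None

    t_chart = build_t_chart(included, plan, recalc_policy)
    p_chart = build_p_chart(visits, classified, plan, period, recalc_policy)

    split = plan[last].start_ts
    bal = balancing_measure(visits, classified, split, window_hours)
    bal_json: dict = {
        "window_hours": bal.window_hours,
        "split_date": str(bal.split_date.date()),
        "pre": {"pathogenic": bal.x_pre, "pairs": bal.n_pre},
        "post": {"pathogenic": bal.x_post, "pairs": bal.n_post},
        "available": bal.available,
    }
    if bal.available:
        c = bal.comparison
        bal_json.update(
            {
                "p_pre_pct": round(100 * c.p1, 1),
                "p_post_pct": round(100 * c.p2, 1),
                "diff_pct": round(100 * c.diff, 1),
                "ci_low_pct": round(100 * c.ci_low, 1),
                "ci_high_pct": round(100 * c.ci_high, 1),
            }
        )

    fin_json = None
    base_entry = rates[first]
    last_entry = rates[last]
    if base_entry["bccr"] and base_entry["bcor"] and last_entry["bcor"]:
        fin = financial_savings(
            n_patients=last_entry["bcor"]["denominator"],
            baseline_bcor=base_entry["bcor"]["rate"],
            baseline_bccr=base_entry["bccr"]["rate"],
            actual_contaminants=last_entry["bccr"]["numerator"] if last_entry["bccr"] else 0,
            charge_per_contaminant=charge_per_contaminant,
        )
        fin_json = {
            "n_patients": fin.n_patients,
            "baseline_bcor": fin.baseline_bcor,
            "baseline_bccr": fin.baseline_bccr,
            "expected_contaminants": fin.expected_contaminants,
            "expected_contaminants_rounded": fin.expected_rounded,
            "actual_contaminants": fin.actual_contaminants,
            "averted": fin.averted,
            "averted_rounded": fin.expected_rounded - fin.actual_contaminants,
            "charge_per_contaminant": fin.charge_per_contaminant,
            "savings": fin.savings,
            "method": "expected = final-phase patients x baseline BCOR x baseline BCCR",
        }

    report = {
        "package_version": __version__,
        "options": {
            "period": period,
            "recalc_policy": recalc_policy,
            "window_hours": window_hours,
            "charge_per_contaminant": charge_per_contaminant,
        },
        "phases": plan.to_records(),
        "counts": {
            "visits": int(len(visits)),
            "cultures": int(len(cultures)),
            "included_cultures": int(len(included)),
            "excluded_cultures": int(len(cultures) - len(included)),
        },
        "rates": rates,
        "relative_decrease": rel,
        "t_chart": {
            "n_events": int(len(t_chart.points_)),
            "center_days": {k: v for k, v in t_chart.center_days_.items()},
            "signals": _signals_json(t_chart.signals_),
        },
        "p_chart": {
            "n_points": int(len(p_chart.points_)),
            "centers": p_chart.centers_,
            "signals": _signals_json(p_chart.signals_),
        },
        "balancing": bal_json,
        "financial": fin_json,
    }
    return {"report": report, "_charts": {"t": t_chart, "p": p_chart}}


def rates_frame(report: dict) -> pd.DataFrame:
    """Flat per-phase rate table (CSV export of the report's rates)."""
    rows = []
    for phase, entry in report["rates"].items():
        row: dict = {"phase": phase}
        for measure in ("bccr", "bcor"):
            e = entry[measure]
            row[f"{measure}_numerator"] = e["numerator"] if e else None
            row[f"{measure}_denominator"] = e["denominator"] if e else None
            row[f"{measure}_pct"] = e["pct"] if e else None
        rows.append(row)
    return pd.DataFrame(rows)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, *, inputs: dict, outputs: dict, config: dict | None = None, seed=None) -> Path:
    """Write manifest.json: digests of inputs/outputs, config snapshot, version, time."""
    manifest = {
        "package_version": __version__,
        "created_at": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": sha256_file(p)} for name, p in inputs.items()},
        "outputs": {name: {"path": str(p), "sha256": sha256_file(p)} for name, p in outputs.items()},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
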