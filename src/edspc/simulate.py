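"""Seeded synthetic ED visit/culture streams.

The generator emulates the statistical structure the analysis assumes,
at the scale of a large urban pediatric ED (~90,000 visits/year):

* visit arrivals are a homogeneous Poisson process;
* each visit independently receives a peripheral blood culture with its
  phase's ordering probability (defaults stepping 4.80% → 4.26% → 3.82%
  → 3.49% across the baseline and three PDSA cycles);
* each culture's outcome is contaminant with the phase's per-culture
  contamination probability (3.02% → 2.30% → 1.58% → 1.17%), pathogen
  with a constant 2%, otherwise no growth after 5 days;
* organisms are drawn uniformly from class-matched pools; ~5% of
  cultures carry a record-level exclusion flag;
* a small fraction of discharged, uncultured visits generate a return
  visit within 48 hours, which may carry a culture and occasionally a
  pathogenic bacteremia — the raw material of the balancing measure.

Everything is driven by a single ``numpy`` Generator with a documented
draw order, so a fixed seed reproduces the output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .organisms import OrganismTable, analysis_set, classify_cultures
from .phases import PhasePlan, default_plan
from .records import EXCLUSION_FLAGS, write_tables

__all__ = ["GeneratorConfig", "SyntheticStream", "generate_stream", "planted_changepoint_stream", "write_stream"]

_MICROS_PER_DAY = 86_400_000_000


def _per_phase(value, n: int, name: str) -> tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),) * n
    vals = tuple(float(v) for v in value)
    if len(vals) != n:
        raise ValueError(f"{name} must have one value per phase ({n}), got {len(vals)}")
    return vals


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic stream.

    Per-phase sequences must align 1:1 with the phase plan; scalars are
    broadcast.  All probabilities live in [0, 1] and per phase
    ``contam_prob + pathogen_prob`` must not exceed 1.
    """

    plan: PhasePlan = field(default_factory=default_plan)
    daily_visits: float = 90_000 / 365
    order_prob: tuple = (0.0480, 0.0426, 0.0382, 0.0349)
    contam_prob: tuple = (0.0302, 0.0230, 0.0158, 0.0117)
    pathogen_prob: float = 0.02
    exclusion_prob: float = 0.05
    return_visit_prob: float = 0.002
    return_culture_prob: float = 0.35
    return_pathogen_prob: tuple[float, float] = (0.036, 0.023)
    return_split_phase: str | None = None  # defaults to the last phase
    disposition_probs: tuple = (0.85, 0.12, 0.02, 0.01)  # discharged/admitted/transferred/other
    los_hours: tuple[float, float] = (1.0, 6.0)
    contaminant_pool: tuple = ()
    pathogen_pool: tuple = ()
    seed: int = 0

    def __post_init__(self):
        n = len(self.plan)
        object.__setattr__(self, "order_prob", _per_phase(self.order_prob, n, "order_prob"))
        object.__setattr__(self, "contam_prob", _per_phase(self.contam_prob, n, "contam_prob"))
        if self.return_split_phase is None:
            object.__setattr__(self, "return_split_phase", self.plan.names[-1])
        if not self.contaminant_pool:
            object.__setattr__(self, "contaminant_pool", OrganismTable.default().labels("contaminant"))
        if not self.pathogen_pool:
            object.__setattr__(self, "pathogen_pool", OrganismTable.default().labels("pathogen"))
        self.validate()

    def validate(self) -> None:
        if self.daily_visits <= 0:
            raise ValueError("daily_visits must be positive")
        probs = list(self.order_prob) + list(self.contam_prob) + [
            self.pathogen_prob, self.exclusion_prob, self.return_visit_prob,
            self.return_culture_prob, *self.return_pathogen_prob,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for cp in self.contam_prob:
            if cp + self.pathogen_prob > 1:
                raise ValueError("contam_prob + pathogen_prob must not exceed 1 in any phase")
        if abs(sum(self.disposition_probs) - 1) > 1e-9 or len(self.disposition_probs) != 4:
            raise ValueError("disposition_probs must be 4 probabilities summing to 1")
        if self.los_hours[0] <= 0 or self.los_hours[1] < self.los_hours[0]:
            raise ValueError("los_hours must be an increasing positive pair")
        self.plan.index(self.return_split_phase)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plan"] = self.plan.to_records()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "plan" in data and not isinstance(data["plan"], PhasePlan):
            data["plan"] = PhasePlan.from_records(data["plan"])
        for key in ("order_prob", "contam_prob", "return_pathogen_prob", "disposition_probs",
                    "los_hours", "contaminant_pool", "pathogen_pool"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of generator parameters")
        return cls.from_dict(data)


@dataclass
class SyntheticStream:
    visits: pd.DataFrame
    cultures: pd.DataFrame
    truth: dict


def _round_us(ts: np.ndarray) -> np.ndarray:
    """Round datetime64[ns] to whole microseconds (CSV-round-trippable)."""
    us = ts.astype("datetime64[us]")
    return us.astype("datetime64[ns]")


def generate_stream(config: GeneratorConfig) -> SyntheticStream:
    """Draw one synthetic stream; identical config ⇒ identical output.

    Draw order (one ``default_rng(seed)``): visit count → arrival
    offsets → lengths of stay → dispositions → per-visit culture
    uniforms → culture placement/outcome/organism/exclusion uniforms →
    per-visit return-visit uniforms (delay, stay, culture, pathogen,
    organism, placement).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = config.plan
    t0 = plan.start_ts.to_datetime64()
    end_excl = plan.end_exclusive_ts.to_datetime64()
    total_days = (end_excl - t0) / np.timedelta64(1, "D")

    # --- base visits --------------------------------------------------------
    n = int(rng.poisson(config.daily_visits * total_days))
    offsets = np.sort(rng.uniform(0.0, total_days, n))
    arrival = _round_us(t0 + (offsets * _MICROS_PER_DAY).astype("timedelta64[us]").astype("timedelta64[ns]"))
    los = rng.uniform(config.los_hours[0], config.los_hours[1], n)
    departure = _round_us(arrival + (los * 3_600_000_000).astype("timedelta64[us]").astype("timedelta64[ns]"))
    departure = np.minimum(departure, end_excl - np.timedelta64(1, "us"))
    departure = np.maximum(departure, arrival)
    disposition = np.array(["discharged", "admitted", "transferred", "other"], dtype=object)[
        rng.choice(4, size=n, p=list(config.disposition_probs))
    ]

    phase_idx = np.searchsorted(
        np.array([p.start_ts.to_datetime64() for p in plan]), arrival, side="right"
    ) - 1
    order_p = np.asarray(config.order_prob)[phase_idx]
    contam_p = np.asarray(config.contam_prob)[phase_idx]

    u_order = rng.uniform(size=n)
    has_culture = u_order < order_p

    # --- base cultures ------------------------------------------------------
    m = int(has_culture.sum())
    frac = rng.uniform(0.1, 0.9, m)
    u_outcome = rng.uniform(size=m)
    u_organism = rng.uniform(size=m)
    u_excl = rng.uniform(size=m)
    flag_pick = rng.integers(0, len(EXCLUSION_FLAGS), size=m)

    c_arr = arrival[has_culture]
    c_dep = departure[has_culture]
    ordered_at = _round_us(c_arr + (frac * (c_dep - c_arr).astype("int64")).astype("int64").astype("timedelta64[ns]"))
    cp = contam_p[has_culture]
    is_contam = u_outcome < cp
    is_path = (~is_contam) & (u_outcome < cp + config.pathogen_prob)
    organism = np.full(m, "", dtype=object)
    cont_pool = np.array(config.contaminant_pool, dtype=object)
    path_pool = np.array(config.pathogen_pool, dtype=object)
    organism[is_contam] = cont_pool[(u_organism[is_contam] * len(cont_pool)).astype(int)]
    organism[is_path] = path_pool[(u_organism[is_path] * len(path_pool)).astype(int)]
    excluded = u_excl < config.exclusion_prob
    flags = np.full(m, "", dtype=object)
    flags[excluded] = np.array(EXCLUSION_FLAGS, dtype=object)[flag_pick[excluded]]

    # --- return visits (balancing-measure raw material) --------------------
    u_ret = rng.uniform(size=n)
    delay_h = rng.uniform(2.0, 46.0, n)
    los2 = rng.uniform(config.los_hours[0], config.los_hours[1], n)
    u_retcult = rng.uniform(size=n)
    u_retpath = rng.uniform(size=n)
    u_retorg = rng.uniform(size=n)
    frac2 = rng.uniform(0.1, 0.9, n)

    eligible = (disposition == "discharged") & ~has_culture & (u_ret < config.return_visit_prob)
    r_arrival = _round_us(departure + (delay_h * 3_600_000_000).astype("timedelta64[us]").astype("timedelta64[ns]"))
    r_departure = _round_us(r_arrival + (los2 * 3_600_000_000).astype("timedelta64[us]").astype("timedelta64[ns]"))
    eligible &= r_departure < end_excl  # keep every event inside the plan span
    ridx = np.nonzero(eligible)[0]

    r_has_culture = u_retcult[ridx] < config.return_culture_prob
    split_ts = plan[config.return_split_phase].start_ts.to_datetime64()
    post = r_arrival[ridx] >= split_ts
    rp = np.where(post, config.return_pathogen_prob[1], config.return_pathogen_prob[0])
    r_phase_idx = np.searchsorted(
        np.array([p.start_ts.to_datetime64() for p in plan]), r_arrival[ridx], side="right"
    ) - 1
    r_contam_p = np.asarray(config.contam_prob)[r_phase_idx]
    r_is_path = u_retpath[ridx] < rp
    r_is_contam = (~r_is_path) & (u_retpath[ridx] < rp + r_contam_p)
    r_organism = np.full(len(ridx), "", dtype=object)
    r_organism[r_is_path] = path_pool[(u_retorg[ridx][r_is_path] * len(path_pool)).astype(int)]
    r_organism[r_is_contam] = cont_pool[(u_retorg[ridx][r_is_contam] * len(cont_pool)).astype(int)]
    r_ordered_at = _round_us(
        r_arrival[ridx]
        + (frac2[ridx] * (r_departure[ridx] - r_arrival[ridx]).astype("int64")).astype("int64").astype("timedelta64[ns]")
    )

    # --- assemble frames with ids in arrival order --------------------------
    n_ret = len(ridx)
    base_patient = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    all_key = np.concatenate([np.arange(n), n + np.arange(n_ret)])
    all_arrival = np.concatenate([arrival, r_arrival[ridx]])
    all_departure = np.concatenate([departure, r_departure[ridx]])
    all_disposition = np.concatenate([disposition, np.full(n_ret, "discharged", dtype=object)])
    all_patient = np.concatenate([base_patient, base_patient[ridx]])
    v_order = np.lexsort((all_key, all_arrival.astype("int64")))
    visit_ids = np.array([f"V{i:07d}" for i in range(n + n_ret)], dtype=object)
    # internal key -> position in the sorted visit table (for culture linkage)
    pos_of_key = np.empty(n + n_ret, dtype=np.int64)
    pos_of_key[all_key[v_order]] = np.arange(n + n_ret)

    visits_out = pd.DataFrame(
        {
            "visit_id": visit_ids,
            "patient_id": all_patient[v_order],
            "arrival": all_arrival[v_order],
            "departure": all_departure[v_order],
            "disposition": all_disposition[v_order],
        }
    )

    n_rc = int(r_has_culture.sum())
    c_key = np.concatenate([np.arange(n)[has_culture], (n + np.arange(n_ret))[r_has_culture]])
    c_ordered = np.concatenate([ordered_at, r_ordered_at[r_has_culture]])
    c_result = np.concatenate(
        [
            np.where(is_contam | is_path, "growth", "no_growth").astype(object),
            np.where((r_is_path | r_is_contam)[r_has_culture], "growth", "no_growth").astype(object),
        ]
    )
    c_organism = np.concatenate([organism, r_organism[r_has_culture]])
    c_flags = np.concatenate([flags, np.full(n_rc, "", dtype=object)])
    c_order = np.lexsort((c_key, c_ordered.astype("int64")))
    vpos = pos_of_key[c_key[c_order]]
    cultures_out = pd.DataFrame(
        {
            "culture_id": np.array([f"C{i:07d}" for i in range(len(c_key))], dtype=object),
            "visit_id": visit_ids[vpos],
            "patient_id": all_patient[v_order][vpos],
            "ordered_at": c_ordered[c_order],
            "result": c_result[c_order],
            "organism": c_organism[c_order],
            "exclusion_flags": c_flags[c_order],
        }
    )

    truth = _build_truth(config, visits_out, cultures_out, ridx, r_has_culture, r_is_path, post)
    return SyntheticStream(visits=visits_out, cultures=cultures_out, truth=truth)


def _build_truth(config, visits, cultures, ridx, r_has_culture, r_is_path, post) -> dict:
    classified = classify_cultures(cultures)
    included = analysis_set(classified)
    plan = config.plan
    per_phase = {}
    v_phase = plan.phase_of(visits["arrival"])
    c_phase = plan.phase_of(classified["ordered_at"])
    i_phase = plan.phase_of(included["ordered_at"])
    for name in plan.names:
        inc = included.loc[i_phase == name]
        n_visits = int((v_phase == name).sum())
        n_inc = len(inc)
        n_contam = int((inc["outcome"] == "contaminant").sum())
        per_phase[name] = {
            "visits": n_visits,
            "cultures_ordered": int((c_phase == name).sum()),
            "cultures_included": n_inc,
            "contaminants_included": n_contam,
            "pathogens_included": int((inc["outcome"] == "pathogen").sum()),
            "bccr_realized": (n_contam / n_inc) if n_inc else None,
            "bcor_realized": (n_inc / n_visits) if n_visits else None,
        }
    qual = r_has_culture
    return {
        "config": config.to_dict(),
        "per_phase": per_phase,
        "balancing": {
            "return_visits": int(len(ridx)),
            "pairs_pre": int((qual & ~post).sum()),
            "pairs_post": int((qual & post).sum()),
            "pathogenic_pre": int((qual & r_is_path & ~post).sum()),
            "pathogenic_post": int((qual & r_is_path & post).sum()),
        },
        "overall": {
            "visits": int(len(visits)),
            "cultures": int(len(cultures)),
            "included_cultures": int(len(included)),
        },
    }


def planted_changepoint_stream(
    config: GeneratorConfig, shift: float, boundary: str | None = None
) -> SyntheticStream:
    """As :func:`generate_stream`, with ``contam_prob`` multiplied by
    ``shift`` from the ``boundary`` phase (default: the last phase)
    onward.  ``shift=1`` reproduces :func:`generate_stream` exactly for
    the same seed.  The truth file records the planted change.
    """
    if shift <= 0:
        raise ValueError("shift must be positive")
    plan = config.plan
    boundary = boundary if boundary is not None else plan.names[-1]
    b = plan.index(boundary)
    scaled = tuple(
        min(cp * shift, 1.0 - config.pathogen_prob) if i >= b else cp
        for i, cp in enumerate(config.contam_prob)
    )
    shifted = dataclasses.replace(config, contam_prob=scaled)
    stream = generate_stream(shifted)
    stream.truth["changepoint"] = {"boundary": boundary, "shift": shift}
    return stream


def write_stream(stream: SyntheticStream, out_dir) -> dict[str, Path]:
    """Write visits.csv, cultures.csv and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(exist_ok=True)
    paths = {
        "visits": out / "visits.csv",
        "cultures": out / "cultures.csv",
        "truth": out / "truth.json",
    }
    write_tables(stream.visits, stream.cultures, paths["visits"], paths["cultures"])
    paths["truth"].write_text(json.dumps(stream.truth, indent=2, sort_keys=True) + "\n")
    return paths
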