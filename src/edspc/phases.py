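"""Study phase plans for interrupted time-series SPC analysis.

A :class:`PhasePlan` is an ordered sequence of named, non-overlapping date
intervals (e.g. a baseline year followed by successive PDSA improvement
cycles).  Every chart and rate in this package is computed per phase, and
special-cause detection in a post-baseline phase is judged against the
limits of the phase before it.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["Phase", "PhasePlan", "default_plan"]


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class Phase:
    """One contiguous study interval; ``end`` is inclusive (calendar days)."""

    name: str
    start: dt.date
    end: dt.date

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.end < self.start:
            raise ValueError(f"phase {self.name!r}: end {self.end} before start {self.start}")

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)

    @property
    def end_exclusive_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.end) + pd.Timedelta(days=1)

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


class PhasePlan:
    """Ordered, strictly increasing, non-overlapping study phases.

    Parameters
    ----------
    phases :
        Iterable of :class:`Phase` (or ``(name, start, end)`` tuples) in
        chronological order.  Phases may be contiguous or gapped but must
        not overlap.
    """

    def __init__(self, phases: Iterable):
        parsed = []
        for p in phases:
            if not isinstance(p, Phase):
                p = Phase(*p)
            parsed.append(p)
        if not parsed:
            raise ValueError("a PhasePlan needs at least one phase")
        names = [p.name for p in parsed]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate phase names: {names}")
        for a, b in zip(parsed, parsed[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"phases {a.name!r} and {b.name!r} overlap or are out of order"
                )
        self.phases: tuple[Phase, ...] = tuple(parsed)
        self._starts = np.array([p.start_ts.to_datetime64() for p in parsed])
        self._ends_excl = np.array([p.end_exclusive_ts.to_datetime64() for p in parsed])

    # -- basic introspection -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.phases)

    @property
    def start_ts(self) -> pd.Timestamp:
        return self.phases[0].start_ts

    @property
    def end_exclusive_ts(self) -> pd.Timestamp:
        return self.phases[-1].end_exclusive_ts

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(f"no phase named {name!r}; have {self.names}")

    def __eq__(self, other) -> bool:
        return isinstance(other, PhasePlan) and self.to_records() == other.to_records()

    def __repr__(self) -> str:
        spans = ", ".join(f"{p.name}: {p.start}..{p.end}" for p in self.phases)
        return f"PhasePlan({spans})"

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no phase named {name!r}; have {self.names}") from None

    def prior(self, name: str) -> str | None:
        """Name of the phase immediately before ``name`` (None for the first)."""
        i = self.index(name)
        return None if i == 0 else self.names[i - 1]

    # -- phase assignment ----------------------------------------------------
    def phase_of(self, when):
        """Map timestamps to phase names.

        Scalar in → scalar out (str or None); array-like in → object ndarray
        with None where the timestamp falls outside every phase (including
        inside a gap between phases).
        """
        scalar = np.isscalar(when) or isinstance(when, (dt.date, dt.datetime, pd.Timestamp, str))
        ts = pd.to_datetime(pd.Series([when] if scalar else when))
        t64 = ts.to_numpy(dtype="datetime64[ns]")
        idx = np.searchsorted(self._starts, t64, side="right") - 1
        valid = idx >= 0
        safe = np.clip(idx, 0, len(self.phases) - 1)
        valid &= t64 < self._ends_excl[safe]
        out = np.full(len(t64), None, dtype=object)
        names = np.array(self.names, dtype=object)
        out[valid] = names[idx[valid]]
        return out[0] if scalar else out

    # -- serialisation -------------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {"name": p.name, "start": p.start.isoformat(), "end": p.end.isoformat()}
            for p in self.phases
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "PhasePlan":
        return cls(Phase(r["name"], r["start"], r["end"]) for r in records)

    @classmethod
    def from_file(cls, path) -> "PhasePlan":
        """Load from YAML or JSON: a list of {name, start, end} mappings."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if isinstance(data, dict) and "phases" in data:
            data = data["phases"]
        if not isinstance(data, list):
            raise ValueError(f"{path}: expected a list of phases")
        return cls.from_records(data)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=2) + "\n")


def default_plan() -> PhasePlan:
    """The default four-phase plan: a baseline year and three PDSA cycles.

    Baseline 2014-07-01..2015-06-30, PDSA1 from 2015-07-01, PDSA2 from
    2015-12-01, PDSA3 2016-07-01..2017-06-30.
    """
    return PhasePlan(
        [
            Phase("baseline", dt.date(2014, 7, 1), dt.date(2015, 6, 30)),
            Phase("pdsa1", dt.date(2015, 7, 1), dt.date(2015, 11, 30)),
            Phase("pdsa2", dt.date(2015, 12, 1), dt.date(2016, 6, 30)),
            Phase("pdsa3", dt.date(2016, 7, 1), dt.date(2017, 6, 30)),
        ]
    )
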