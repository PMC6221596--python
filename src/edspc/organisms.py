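"""Organism classification and the culture analysis set.

A positive blood culture is either a true *pathogen* or a *contaminant*
(skin or environmental flora introduced at venipuncture).  The mapping
from organism label to class is data, not algorithm: the package ships a
default table assembled from the conventional pediatric blood-culture
literature (coagulase-negative staphylococci, *Micrococcus*, *Bacillus*
other than *B. anthracis*, diphtheroids, *Cutibacterium*, and
viridans-group streptococci as contaminants; *S. aureus*,
*S. pneumoniae*, enteric gram-negatives, *N. meningitidis*,
*H. influenzae*, group A/B streptococci, enterococci, *P. aeruginosa*
and *Candida* as pathogens), and any study can override it with a
two-column CSV (``organism,class``).

Classification is strict: an organism label absent from the table raises
:class:`ClassificationError` listing the unknown labels — never a silent
default — because a mislabelled pathogen would corrupt both the
contamination rate and the missed-bacteremia balancing measure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ClassificationError",
    "OrganismTable",
    "CultureClassifier",
    "classify_cultures",
    "analysis_set",
    "OUTCOMES",
]

OUTCOMES = ("negative", "pathogen", "contaminant")


class ClassificationError(ValueError):
    """Raised when a culture's organism label is absent from the table."""


def _normalize(label: str) -> str:
    return " ".join(str(label).split()).casefold()


_DEFAULT_CONTAMINANTS = (
    "coagulase-negative Staphylococcus",
    "Staphylococcus epidermidis",
    "Staphylococcus hominis",
    "Staphylococcus capitis",
    "Staphylococcus haemolyticus",
    "Micrococcus species",
    "Micrococcus luteus",
    "Bacillus species",
    "Bacillus cereus",
    "diphtheroids",
    "Corynebacterium species",
    "Cutibacterium acnes",
    "Propionibacterium acnes",
    "viridans group Streptococcus",
    "Streptococcus mitis",
    "Streptococcus salivarius",
)

_DEFAULT_PATHOGENS = (
    "Staphylococcus aureus",
    "Streptococcus pneumoniae",
    "Streptococcus pyogenes",
    "group A Streptococcus",
    "Streptococcus agalactiae",
    "group B Streptococcus",
    "Escherichia coli",
    "Klebsiella pneumoniae",
    "Klebsiella oxytoca",
    "Enterobacter cloacae",
    "Salmonella species",
    "Neisseria meningitidis",
    "Haemophilus influenzae",
    "Enterococcus faecalis",
    "Enterococcus faecium",
    "Pseudomonas aeruginosa",
    "Candida albicans",
    "Candida parapsilosis",
)


class OrganismTable:
    """Case- and whitespace-insensitive organism → class lookup.

    Parameters
    ----------
    entries :
        Mapping of organism label to ``"contaminant"`` or ``"pathogen"``.
        Labels are normalised (collapse whitespace, casefold); two labels
        normalising to the same key with different classes is an error.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for label, cls in entries.items():
            if cls not in ("contaminant", "pathogen"):
                raise ValueError(f"organism {label!r}: class must be contaminant or pathogen, got {cls!r}")
            key = _normalize(label)
            if key in self._entries and self._entries[key] != cls:
                raise ValueError(f"organism {label!r} maps to both classes after normalisation")
            self._entries[key] = cls
            self._display.setdefault(key, " ".join(str(label).split()))
        if not self._entries:
            raise ValueError("organism table is empty")

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return _normalize(label) in self._entries

    def classify(self, label: str) -> str:
        try:
            return self._entries[_normalize(label)]
        except KeyError:
            raise ClassificationError(f"organism not in classification table: {label!r}") from None

    def labels(self, cls: str | None = None) -> tuple[str, ...]:
        return tuple(
            self._display[k] for k, v in sorted(self._entries.items()) if cls is None or v == cls
        )

    @classmethod
    def default(cls) -> "OrganismTable":
        entries = {name: "contaminant" for name in _DEFAULT_CONTAMINANTS}
        entries.update({name: "pathogen" for name in _DEFAULT_PATHOGENS})
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "OrganismTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("organism", "class"):
            if col not in df.columns:
                raise ValueError(f"organism table {path} is missing column {col!r}")
        return cls(dict(zip(df["organism"], df["class"])))

    def to_csv(self, path) -> None:
        rows = [{"organism": self._display[k], "class": v} for k, v in sorted(self._entries.items())]
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


class CultureClassifier(BaseEstimator, TransformerMixin):
    """Transformer adding ``outcome`` and ``included`` columns to a culture table.

    ``outcome`` is ``negative`` for no-growth cultures and otherwise the
    organism's class from the table; ``included`` is True exactly when the
    record carries no exclusion flag (central line, VP shunt, oncologic
    condition, neutropenia, transplant history).

    Parameters
    ----------
    organism_table : OrganismTable, optional
        Defaults to :meth:`OrganismTable.default`.
    """

    def __init__(self, organism_table: OrganismTable | None = None):
        self.organism_table = organism_table

    def fit(self, X: pd.DataFrame, y=None):
        self.table_ = self.organism_table or OrganismTable.default()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "table_"):
            self.fit(X)
        out = X.copy()
        growth = out["result"] == "growth"
        unknown = sorted(
            {lab for lab in out.loc[growth, "organism"].unique() if lab not in self.table_}
        )
        if unknown:
            raise ClassificationError(
                "organism label(s) not in classification table: " + ", ".join(repr(u) for u in unknown)
            )
        outcome = pd.Series("negative", index=out.index, dtype=object)
        outcome[growth] = out.loc[growth, "organism"].map(self.table_.classify)
        out["outcome"] = outcome
        out["included"] = out["exclusion_flags"].fillna("").astype(str).str.strip() == ""
        return out


def classify_cultures(cultures: pd.DataFrame, table: OrganismTable | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`CultureClassifier`."""
    return CultureClassifier(table).fit(cultures).transform(cultures)


def analysis_set(classified: pd.DataFrame) -> pd.DataFrame:
    """Cultures eligible for analysis: no exclusion flags, in time order.

    Records are sorted by ``ordered_at`` ascending with ties broken by
    ``culture_id``; the operation is idempotent.
    """
    kept = classified.loc[classified["included"]]
    return kept.sort_values(["ordered_at", "culture_id"], kind="mergesort").reset_index(drop=True)
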