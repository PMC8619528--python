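"""Core data containers shared by every pipeline stage.

The central object is :class:`ActivityTable`, a samples × taxa matrix of
16S rRNA transcript-derived counts ("activity").  Sample metadata, taxonomic
lineages and the cage-experiment ledgers (survival, feeding) are the other
first-class citizens.  All tabular objects are thin, validated wrappers
around :class:`pandas.DataFrame` so they interoperate with the scientific
Python stack without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GUT_SECTIONS",
    "DOSES_PPB",
    "RANKS",
    "ActivityTable",
    "Lineage",
    "ValidationError",
    "validate_metadata",
    "validate_survival_ledger",
    "validate_feeding_ledger",
    "METADATA_COLUMNS",
    "SURVIVAL_COLUMNS",
    "FEEDING_COLUMNS",
]

#: Gut sections dissected in the cage experiment (the crop is not analysed).
GUT_SECTIONS: tuple[str, ...] = ("midgut", "ileum", "rectum")

#: Clothianidin doses in the syrup, parts per billion; 0 is the unexposed control.
DOSES_PPB: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0)

#: Taxonomic ranks, ordered from the most inclusive to the most specific.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

METADATA_COLUMNS = (
    "sample_id",
    "cage",
    "gut_section",
    "dose_ppb",
    "replicate",
    "timepoint_day",
)
SURVIVAL_COLUMNS = ("group", "cage", "day", "n_at_risk", "deaths", "censored")
FEEDING_COLUMNS = ("group", "cage", "day", "syrup_consumed", "alive_prev", "alive_now")


class ValidationError(ValueError):
    """An input violated a structural invariant of one of the data types."""


@dataclass
class ActivityTable:
    """Samples × taxa activity matrix.

    Parameters
    ----------
    counts
        DataFrame with sample ids on the index, taxon (ASV or genus) ids as
        columns, non-negative numeric entries.  Stored as float so both raw
        counts and normalised activities fit; integrality is enforced only
        where an estimator requires it (e.g. Chao1).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("activity table contains non-finite entries")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at sample {idx[i]!r}, taxon {cols[j]!r}"
            )
        if len(cols) and (vals.sum(axis=1) == 0).any():
            bad = idx[vals.sum(axis=1) == 0].tolist()
            raise ValidationError(f"all-zero samples must be dropped at read: {bad}")

    # -- conveniences ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def relative(self) -> "ActivityTable":
        """Per-sample relative activity (rows sum to 1)."""
        rel = self.counts.div(self.counts.sum(axis=1), axis=0)
        return ActivityTable(rel)

    def subset(self, sample_ids: Iterable[str]) -> "ActivityTable":
        wanted = [s for s in sample_ids]
        missing = [s for s in wanted if s not in self.counts.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return ActivityTable(self.counts.loc[wanted])

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, ActivityTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass(frozen=True)
class Lineage:
    """A seven-rank taxonomic lineage, filled from the top down without gaps.

    Empty strings mark unassigned ranks; an all-empty lineage is the
    "unassigned" sentinel used for ASVs that could not be classified.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValidationError(
                f"lineage needs {len(RANKS)} ranks, got {len(self.names)}"
            )
        seen_empty = False
        for name in self.names:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValidationError(
                    f"lineage has a gap (named rank below an empty one): {self.names}"
                )

    @classmethod
    def from_ranks(cls, ranks: Mapping[str, str], fill_gaps: bool = True) -> "Lineage":
        """Build from a rank→name mapping.

        With ``fill_gaps`` (default), a missing intermediate rank inherits the
        parent's name with an ``unclassified_`` prefix so rank-walks never gap;
        trailing missing ranks stay empty.
        """
        names = [str(ranks.get(r, "") or "") for r in RANKS]
        deepest = max((i for i, n in enumerate(names) if n), default=-1)
        if fill_gaps and deepest >= 0:
            for i in range(deepest + 1):
                if not names[i]:
                    parent = names[i - 1] if i > 0 else "root"
                    names[i] = f"unclassified_{parent}"
        return cls(tuple(names))

    @classmethod
    def unassigned(cls) -> "Lineage":
        return cls(("",) * len(RANKS))

    @property
    def is_unassigned(self) -> bool:
        return all(n == "" for n in self.names)

    @property
    def assigned_rank(self) -> str | None:
        """Deepest non-empty rank, or None for the unassigned sentinel."""
        for rank, name in zip(reversed(RANKS), reversed(self.names)):
            if name:
                return rank
        return None

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    @property
    def genus(self) -> str:
        return self.name_at("genus")

    def truncate(self, depth: int) -> "Lineage":
        """Keep the first ``depth`` ranks, blanking the rest."""
        return Lineage(tuple(self.names[:depth]) + ("",) * (len(RANKS) - depth))

    def as_dict(self) -> dict[str, str]:
        return dict(zip(RANKS, self.names))


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing required columns: {missing}")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample metadata table.

    Enforces the study design enumerations: gut_section must be one of
    midgut/ileum/rectum and dose one of 0, 0.1, 1, 10 ppb.
    """
    _require_columns(meta, METADATA_COLUMNS, "metadata")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
    bad_sections = sorted(set(meta["gut_section"]) - set(GUT_SECTIONS))
    if bad_sections:
        raise ValidationError(
            f"unknown gut_section values {bad_sections}; expected {GUT_SECTIONS}"
        )
    meta["dose_ppb"] = meta["dose_ppb"].astype(float)
    bad_doses = sorted(set(meta["dose_ppb"]) - set(DOSES_PPB))
    if bad_doses:
        raise ValidationError(
            f"unknown dose_ppb values {bad_doses}; expected {DOSES_PPB}"
        )
    meta["replicate"] = meta["replicate"].astype(int)
    meta["timepoint_day"] = meta["timepoint_day"].astype(int)
    return meta


def validate_survival_ledger(ledger: pd.DataFrame, horizon: int | None = None) -> pd.DataFrame:
    """Validate a per-cage per-day survival ledger.

    Each row records, for one cage on one day: the number of bees at risk at
    the start of the day, deaths during the day, and bees censored (removed,
    e.g. weekly sampling) at the end of the day.
    """
    _require_columns(ledger, SURVIVAL_COLUMNS, "survival ledger")
    ledger = ledger.copy()
    for col in ("day", "n_at_risk", "deaths", "censored"):
        ledger[col] = ledger[col].astype(int)
    if (ledger["deaths"] + ledger["censored"] > ledger["n_at_risk"]).any():
        raise ValidationError("deaths + censored exceed n_at_risk in survival ledger")
    if (ledger["day"] < 0).any():
        raise ValidationError("negative day in survival ledger")
    if horizon is not None and (ledger["day"] > horizon).any():
        raise ValidationError(f"day beyond horizon {horizon} in survival ledger")
    for (_, _), sub in ledger.groupby(["group", "cage"]):
        risk = sub.sort_values("day")["n_at_risk"].to_numpy()
        if (np.diff(risk) > 0).any():
            raise ValidationError("n_at_risk increases within a cage over days")
    return ledger


def validate_feeding_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    _require_columns(ledger, FEEDING_COLUMNS, "feeding ledger")
    ledger = ledger.copy()
    ledger["syrup_consumed"] = ledger["syrup_consumed"].astype(float)
    if (ledger["syrup_consumed"] < 0).any():
        raise ValidationError("negative syrup consumption in feeding ledger")
    if (ledger["alive_now"] > ledger["alive_prev"]).any():
        raise ValidationError("alive_now exceeds alive_prev in feeding ledger")
    if (ledger["alive_now"] < 0).any():
        raise ValidationError("negative alive count in feeding ledger")
    return ledger


def condition_samples(
    meta: pd.DataFrame, section: str, dose_ppb: float
) -> list[str]:
    """Sample ids belonging to one (gut section, dose) condition subset."""
    mask = (meta["gut_section"] == section) & (meta["dose_ppb"] == float(dose_ppb))
    return meta.loc[mask, "sample_id"].tolist()
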