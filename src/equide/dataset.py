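"""Feed data model and I/O.

A feed (a commercial compound feed or a forage-plus-concentrate diet) is
described by its Weende proximate composition — crude protein (CP), crude
fiber (CF), nitrogen-free extract (NFE) and crude fat / ether extract (EE),
all as % of dry matter — optionally by the corresponding digestible nutrient
fractions (crude fraction x apparent digestibility coefficient, % of dry
matter), and by its observed digestible energy (DE, kcal/kg dry matter)
measured in an in vivo digestion trial.

The module ships a 32-feed reference dataset compiled from six published
digestion-trial reports (:func:`load_table1`), and reads/writes feed tables
as plain CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "ProximateComposition",
    "DigestibleFractions",
    "FeedRecord",
    "Dataset",
    "FeedTableFormatError",
    "ValidationError",
    "load_table1",
    "read_feed_table",
    "write_feed_table",
    "FEED_TABLE_COLUMNS",
]

#: Mandatory column order of the CSV feed-table format.
FEED_TABLE_COLUMNS = [
    "id", "source", "kind",
    "cp", "cf", "nfe", "ee",
    "dcp", "dcf", "dnfe", "dee",
    "de_obs",
]

#: Cell spellings accepted as "no value" in digestible-nutrient columns.
NA_SPELLINGS = {"", "NA", "Not available"}

VALID_KINDS = ("mixed diet", "mixed feed")


class ValidationError(ValueError):
    """A record or dataset violates a domain invariant."""


class FeedTableFormatError(ValueError):
    """A feed-table file does not conform to the CSV dialect."""


@dataclass(frozen=True)
class ProximateComposition:
    """Weende proximate composition, % of dry matter.

    The four organic fractions must be non-negative and sum to at most
    100 % DM (the remainder is ash plus, for partial analyses, anything
    not reported).
    """

    cp: float   #: crude protein
    cf: float   #: crude fiber
    nfe: float  #: nitrogen-free extract
    ee: float   #: crude fat (ether extract)

    def __post_init__(self) -> None:
        for name in ("cp", "cf", "nfe", "ee"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.total > 100.0 + 1e-9:
            raise ValidationError(
                f"organic fractions sum to {self.total:.2f} % DM (> 100)"
            )

    @property
    def total(self) -> float:
        """Sum of the organic fractions (organic matter, % DM)."""
        return self.cp + self.cf + self.nfe + self.ee


@dataclass(frozen=True)
class DigestibleFractions:
    """Digestible nutrient fractions, % of dry matter.

    Each digestible fraction is the crude fraction multiplied by its
    apparent digestibility coefficient, so it can never exceed the crude
    fraction; that cross-constraint is enforced by :class:`FeedRecord`.
    """

    dcp: float
    dcf: float
    dnfe: float
    dee: float

    def __post_init__(self) -> None:
        for name in ("dcp", "dcf", "dnfe", "dee"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        """Digestible organic matter, % DM."""
        return self.dcp + self.dcf + self.dnfe + self.dee


@dataclass(frozen=True)
class FeedRecord:
    """One mixed feed or diet with known observed digestible energy.

    Parameters
    ----------
    id
        Positive integer identifier, unique within a dataset.
    source
        Free-text citation label of the digestion trial.
    kind
        ``"mixed diet"`` (forage plus concentrate) or ``"mixed feed"``
        (compound feed). Informational only; no computation branches on it.
    composition
        Proximate composition, % DM.
    digestible
        Digestible nutrient fractions, % DM, or ``None`` when the source
        did not report them. Either all four are present or none.
    de_observed
        Observed digestible energy, kcal/kg DM (> 0).
    reference_predictions
        Optional mapping of equation name to the DE value printed in the
        source compilation. Reference metadata for cross-checking only;
        never an input to any computation.
    """

    id: int
    source: str
    kind: str
    composition: ProximateComposition
    de_observed: float
    digestible: Optional[DigestibleFractions] = None
    reference_predictions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValidationError(f"record id must be positive, got {self.id}")
        if self.kind not in VALID_KINDS:
            raise ValidationError(
                f"record {self.id}: kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if not math.isfinite(self.de_observed) or self.de_observed <= 0:
            raise ValidationError(
                f"record {self.id}: de_observed must be > 0, got {self.de_observed}"
            )
        if self.digestible is not None:
            pairs = [
                ("dcp", "cp"), ("dcf", "cf"), ("dnfe", "nfe"), ("dee", "ee"),
            ]
            for dname, cname in pairs:
                d = getattr(self.digestible, dname)
                c = getattr(self.composition, cname)
                if d > c + 1e-9:
                    raise ValidationError(
                        f"record {self.id}: {dname} ({d}) exceeds {cname} ({c})"
                    )

    @property
    def has_digestible(self) -> bool:
        return self.digestible is not None


@dataclass(frozen=True)
class Dataset:
    """Ordered, non-empty collection of :class:`FeedRecord` with unique ids."""

    records: tuple[FeedRecord, ...]
    name: str = "dataset"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("dataset must contain at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FeedRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> FeedRecord:
        return self.records[i]

    def get(self, record_id: int) -> FeedRecord:
        """Return the record with the given id."""
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(f"no record with id {record_id}")

    def complete(self) -> "Dataset":
        """Sub-dataset of records that carry digestible nutrient fractions."""
        recs = tuple(r for r in self.records if r.has_digestible)
        return Dataset(recs, name=f"{self.name}[complete]")

    def to_frame(self, include_reference: bool = False) -> pd.DataFrame:
        """Tabular view (one row per feed), columns as in the CSV format."""
        rows = []
        for r in self.records:
            row = {
                "id": r.id, "source": r.source, "kind": r.kind,
                "cp": r.composition.cp, "cf": r.composition.cf,
                "nfe": r.composition.nfe, "ee": r.composition.ee,
                "dcp": r.digestible.dcp if r.has_digestible else None,
                "dcf": r.digestible.dcf if r.has_digestible else None,
                "dnfe": r.digestible.dnfe if r.has_digestible else None,
                "dee": r.digestible.dee if r.has_digestible else None,
                "de_obs": r.de_observed,
            }
            if include_reference:
                for key, val in r.reference_predictions.items():
                    row[f"pred_{key}"] = val
            rows.append(row)
        return pd.DataFrame(rows)


def _record_from_row(row: pd.Series, *, reference_cols: Iterable[str] = ()) -> FeedRecord:
    comp = ProximateComposition(
        cp=float(row["cp"]), cf=float(row["cf"]),
        nfe=float(row["nfe"]), ee=float(row["ee"]),
    )
    dig_vals = [row[c] for c in ("dcp", "dcf", "dnfe", "dee")]
    present = [pd.notna(v) for v in dig_vals]
    if any(present) and not all(present):
        raise ValidationError(
            f"record {row['id']}: digestible fractions must be all present or all absent"
        )
    digestible = (
        DigestibleFractions(*(float(v) for v in dig_vals)) if all(present) else None
    )
    ref = {
        c.removeprefix("pred_"): float(row[c])
        for c in reference_cols
        if pd.notna(row.get(c))
    }
    return FeedRecord(
        id=int(row["id"]),
        source=str(row["source"]),
        kind=str(row["kind"]),
        composition=comp,
        digestible=digestible,
        de_observed=float(row["de_obs"]),
        reference_predictions=ref,
    )


def _dataset_from_frame(df: pd.DataFrame, name: str) -> Dataset:
    missing = [c for c in FEED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FeedTableFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    reference_cols = [c for c in df.columns if c.startswith("pred_")]
    records = []
    for _, row in df.iterrows():
        records.append(_record_from_row(row, reference_cols=reference_cols))
    return Dataset(tuple(records), name=name)


def read_feed_table(path: str | Path, name: Optional[str] = None) -> Dataset:
    """Read and validate a CSV feed table.

    The format is comma-separated, UTF-8, period decimal mark, with a
    mandatory header row and the columns ``id, source, kind, cp, cf, nfe,
    ee, dcp, dcf, dnfe, dee, de_obs``. Digestible-nutrient cells may be
    empty, ``NA`` or ``Not available``; an empty block yields a record
    without digestible fractions. Extra ``pred_*`` columns are read as
    reference-prediction metadata.

    Raises
    ------
    FeedTableFormatError
        If a mandatory column is missing.
    ValidationError
        If any record violates a domain invariant; the message names the
        record id and the rule.
    """
    path = Path(path)
    df = pd.read_csv(
        path, na_values=sorted(NA_SPELLINGS), keep_default_na=False,
        skipinitialspace=True,
    )
    return _dataset_from_frame(df, name=name or path.stem)


def write_feed_table(ds: Dataset, path: str | Path, *, include_reference: bool = True) -> None:
    """Write a dataset as a CSV feed table readable by :func:`read_feed_table`.

    Absent digestible fractions are written as empty cells.
    """
    df = ds.to_frame(include_reference=include_reference)
    df.to_csv(path, index=False, na_rep="")


def load_table1() -> Dataset:
    """Load the packaged 32-feed evaluation dataset.

    The fixture compiles, from six published in vivo digestion-trial
    reports, 24 mixed diets and 8 mixed feeds with proximate composition,
    digestible nutrient fractions where the source reported them (24 of
    the 32 records), and observed DE. The DE values printed alongside in
    the source compilation for the two prediction equations ride along in
    ``reference_predictions`` ("ns" and "zk") for cross-checking; the
    package always recomputes predictions from the equation coefficients.
    """
    with resources.files("equide.data").joinpath("table1.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, na_values=sorted(NA_SPELLINGS), keep_default_na=False)
    return _dataset_from_frame(df, name="table1")
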