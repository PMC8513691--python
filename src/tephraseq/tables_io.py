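"""Readers, writers and domain types for ASV feature tables, sample metadata
and taxonomy.

The central object of every downstream stage is the :class:`FeatureTable`, an
integer count matrix of amplicon sequence variants (features, rows) by samples
(columns).  Sample metadata records the habitat each sample came from (drill
core, borehole fluid, fumarole, seawater, drilling fluid, or negative control)
together with collection depth and in situ temperature; taxonomy records hold
a seven-rank lineage per feature with a single canonical ``UNASSIGNED``
sentinel for missing names.

All on-disk formats are plain TSV (UTF-8, LF).  Feature tables are stored
features-as-rows with a required ``#feature_id`` header token; tables exported
samples-as-rows (the common denoiser orientation) are auto-detected and
transposed on read.  Sample and feature order is preserved from the input
files everywhere — no implicit sorting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: strings that map to the UNASSIGNED sentinel on read (case-insensitive)
_MISSING_TAXON_NAMES = {"", "na", "n/a", "nan", "unclassified", "unknown", "unassigned"}

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

FEATURE_ID_TOKEN = "#feature_id"


class TableFormatError(ValueError):
    """Raised when an input file violates the documented format."""


class SampleType(str, Enum):
    DRILL_CORE = "drill_core"
    BOREHOLE_FLUID = "borehole_fluid"
    FUMAROLE = "fumarole"
    SEAWATER = "seawater"
    DRILLING_FLUID = "drilling_fluid"
    NEGATIVE_CONTROL = "negative_control"


class CoreCategory(str, Enum):
    DC_1 = "DC_1"
    DC_2 = "DC_2"
    DC_3 = "DC_3"
    DC_4 = "DC_4"
    NONE = "none"


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata.

    ``core_category`` is meaningful only for drill cores (depth category
    DC_1–DC_4 along the borehole); ``depth_m`` is meters below surface and
    ``temperature_C`` the in situ collection temperature, either may be
    missing (None).  ``is_control`` is true exactly for negative controls.
    """

    sample_id: str
    sample_type: SampleType
    core_category: CoreCategory = CoreCategory.NONE
    depth_m: float | None = None
    temperature_C: float | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.core_category != CoreCategory.NONE and self.sample_type != SampleType.DRILL_CORE:
            raise TableFormatError(
                f"sample {self.sample_id!r}: core_category {self.core_category.value!r} "
                "is only valid for drill_core samples"
            )
        if self.is_control != (self.sample_type == SampleType.NEGATIVE_CONTROL):
            raise TableFormatError(
                f"sample {self.sample_id!r}: is_control must be true iff "
                "sample_type is negative_control"
            )
        if self.depth_m is not None and self.depth_m < 0:
            raise TableFormatError(f"sample {self.sample_id!r}: negative depth")


@dataclass(frozen=True)
class TaxonomyRecord:
    """Seven-rank lineage of one feature; absent ranks hold ``UNASSIGNED``."""

    feature_id: str
    kingdom: str = UNASSIGNED
    phylum: str = UNASSIGNED
    class_: str = UNASSIGNED
    order: str = UNASSIGNED
    family: str = UNASSIGNED
    genus: str = UNASSIGNED
    species: str = UNASSIGNED

    def rank(self, name: str) -> str:
        key = "class_" if name == "class" else name
        return getattr(self, key)

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(self.rank(r) for r in RANKS)


class FeatureTable:
    """Integer count matrix of features (rows) by samples (columns).

    Thin wrapper over a pandas DataFrame that enforces the invariants:
    unique identifiers, non-negative integer counts, dimensions consistent
    with the identifier lists.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise TableFormatError(f"duplicate feature id {dup!r}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()][0]
            raise TableFormatError(f"duplicate sample id {dup!r}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise TableFormatError("counts must be integers")
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self._df = pd.DataFrame(
            arr.astype(np.int64) if arr.size else arr,
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def sample(self, sample_id: str) -> np.ndarray:
        return self._df[sample_id].to_numpy()

    def column_sums(self) -> pd.Series:
        return self._df.sum(axis=0)

    # -- transforms (all order-preserving) ---------------------------------
    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return FeatureTable(self._df[keep])

    def drop_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        drop = set(sample_ids)
        return FeatureTable(self._df[[s for s in self.sample_ids if s not in drop]])

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        keep = set(feature_ids)
        return FeatureTable(self._df.loc[[f for f in self.feature_ids if f in keep]])

    def drop_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        drop = set(feature_ids)
        return FeatureTable(self._df.loc[[f for f in self.feature_ids if f not in drop]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self._df.equals(other._df)


@dataclass
class Dataset:
    """A feature table harmonized with its metadata and taxonomy maps."""

    table: FeatureTable
    metadata: dict[str, SampleRecord]
    taxonomy: dict[str, TaxonomyRecord]

    def __post_init__(self) -> None:
        for s in self.table.sample_ids:
            if s not in self.metadata:
                raise TableFormatError(f"sample {s!r} has no metadata record")
        for f in self.table.feature_ids:
            if f not in self.taxonomy:
                raise TableFormatError(f"feature {f!r} has no taxonomy record")

    def samples_of_type(self, *types: SampleType) -> list[str]:
        wanted = set(types)
        return [s for s in self.table.sample_ids if self.metadata[s].sample_type in wanted]


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a TSV count table.

    The first header cell decides the orientation: ``#feature_id`` means
    features-as-rows (canonical); anything else is treated as a
    samples-as-rows export and transposed.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    seen: set[str] = set()
    for cell in header[1:]:
        if cell in seen:
            raise TableFormatError(f"{path.name}: duplicate column id {cell!r}")
        seen.add(cell)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.columns = header[1:]  # undo pandas' duplicate-name mangling
    transposed = header[0].strip() != FEATURE_ID_TOKEN
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                val = int(str(cell))
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path.name}: non-integer count {cell!r} at row {row!r}, column {col!r}"
                ) from None
            if val < 0:
                raise TableFormatError(
                    f"{path.name}: negative count at row {row!r}, column {col!r}"
                )
            parsed.loc[row, col] = val
    if transposed:
        parsed = parsed.T
    parsed.index.name = None
    return FeatureTable(parsed.astype(np.int64))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = FEATURE_ID_TOKEN
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE or v == "nan":
        return False
    raise TableFormatError(f"{context}: cannot parse boolean {value!r}")


def _parse_optional_float(value, context: str) -> float | None:
    if value is None:
        return None
    v = str(value).strip()
    if v == "" or v.lower() in {"na", "n/a", "nan", "none"}:
        return None
    try:
        return float(v)
    except ValueError:
        raise TableFormatError(f"{context}: cannot parse number {value!r}") from None


def read_metadata(path: str | Path) -> dict[str, SampleRecord]:
    """Read the sample metadata TSV into an ordered map sample_id -> record."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("sample_id", "sample_type"):
        if required not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {required!r}")
    records: dict[str, SampleRecord] = {}
    allowed = sorted(t.value for t in SampleType)
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if not sid:
            raise TableFormatError(f"{path.name}: empty sample_id")
        if sid in records:
            raise TableFormatError(f"{path.name}: duplicate sample id {sid!r}")
        stype_raw = str(row["sample_type"]).strip()
        try:
            stype = SampleType(stype_raw)
        except ValueError:
            raise TableFormatError(
                f"{path.name}: unknown sample_type {stype_raw!r} for {sid!r}; "
                f"allowed values: {', '.join(allowed)}"
            ) from None
        cat_raw = str(row.get("core_category", "") or "").strip()
        category = CoreCategory.NONE if cat_raw in {"", "none", "NA"} else CoreCategory(cat_raw)
        depth = _parse_optional_float(row.get("depth_m"), f"{path.name} sample {sid!r}")
        temp = _parse_optional_float(row.get("temperature_C"), f"{path.name} sample {sid!r}")
        if "is_control" in df.columns:
            is_control = _parse_bool(row["is_control"], f"{path.name} sample {sid!r}")
        else:
            is_control = stype == SampleType.NEGATIVE_CONTROL
        records[sid] = SampleRecord(
            sample_id=sid,
            sample_type=stype,
            core_category=category,
            depth_m=depth,
            temperature_C=temp,
            is_control=is_control,
        )
    return records


def write_metadata(metadata: Mapping[str, SampleRecord], path: str | Path) -> None:
    rows = []
    for rec in metadata.values():
        rows.append(
            {
                "sample_id": rec.sample_id,
                "sample_type": rec.sample_type.value,
                "core_category": rec.core_category.value,
                "depth_m": "" if rec.depth_m is None else rec.depth_m,
                "temperature_C": "" if rec.temperature_C is None else rec.temperature_C,
                "is_control": "true" if rec.is_control else "false",
            }
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# taxonomy I/O
# ---------------------------------------------------------------------------

def _clean_rank(name: str) -> str:
    """Strip rank prefixes (``k__`` style) and whitespace; map missing names
    to the UNASSIGNED sentinel."""
    v = str(name).strip()
    if len(v) >= 3 and v[1:3] == "__" and v[0].isalpha():
        v = v[3:].strip()
    if v.lower() in _MISSING_TAXON_NAMES:
        return UNASSIGNED
    return v


def _record_from_ranks(feature_id: str, ranks: list[str]) -> TaxonomyRecord:
    if len(ranks) > 7:
        raise TableFormatError(
            f"feature {feature_id!r}: {len(ranks)} lineage segments (maximum 7)"
        )
    cleaned = [_clean_rank(r) for r in ranks]
    cleaned += [UNASSIGNED] * (7 - len(cleaned))
    return TaxonomyRecord(
        feature_id,
        kingdom=cleaned[0],
        phylum=cleaned[1],
        class_=cleaned[2],
        order=cleaned[3],
        family=cleaned[4],
        genus=cleaned[5],
        species=cleaned[6],
    )


def read_taxonomy(
    path: str | Path, dialect: str | None = None
) -> dict[str, TaxonomyRecord]:
    """Read a taxonomy TSV in either the seven-column or the ';'-separated
    lineage-string dialect.  When ``dialect`` is None it is inferred from the
    column count (>=8 columns means seven_column)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, header=0)
    if dialect is None:
        dialect = "seven_column" if df.shape[1] >= 8 else "lineage_string"
    if dialect not in {"seven_column", "lineage_string"}:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    records: dict[str, TaxonomyRecord] = {}
    for _, row in df.iterrows():
        fid = str(row.iloc[0]).strip()
        if not fid:
            raise TableFormatError(f"{path.name}: empty feature id")
        if fid in records:
            raise TableFormatError(f"{path.name}: duplicate feature id {fid!r}")
        if dialect == "seven_column":
            ranks = [row.iloc[i] for i in range(1, min(8, df.shape[1]))]
        else:
            lineage = str(row.iloc[1])
            ranks = [seg for seg in lineage.split(";")] if lineage.strip() else []
            ranks = [seg for seg in ranks if seg.strip() != ""] or [""]
        records[fid] = _record_from_ranks(fid, ranks)
    return records


def write_taxonomy(taxonomy: Mapping[str, TaxonomyRecord], path: str | Path) -> None:
    rows = [
        {"feature_id": rec.feature_id, **dict(zip(RANKS, rec.as_tuple()))}
        for rec in taxonomy.values()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(
    table: FeatureTable,
    metadata: Mapping[str, SampleRecord],
    taxonomy: Mapping[str, TaxonomyRecord],
) -> Dataset:
    """Join table, metadata and taxonomy into a validated :class:`Dataset`.

    Samples lacking a metadata record are dropped with a logged warning;
    features lacking taxonomy receive all-UNASSIGNED records.  Idempotent.
    """
    known = [s for s in table.sample_ids if s in metadata]
    missing = [s for s in table.sample_ids if s not in metadata]
    if missing:
        logger.warning("dropping %d sample(s) without metadata: %s", len(missing), missing)
    if not known:
        raise TableFormatError("no annotated samples")
    out_table = table.select_samples(known)
    out_meta = {s: metadata[s] for s in known}
    out_tax = {
        f: taxonomy.get(f, TaxonomyRecord(f)) for f in out_table.feature_ids
    }
    return Dataset(table=out_table, metadata=out_meta, taxonomy=out_tax)
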