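"""Readers, writers and validated containers for every file the pipeline touches.

Formats are deliberately plain: TSV for matrices and tables (UTF-8, no
quoting), Broad-dialect GMT for gene sets, JSON for the literature count
cache.  All readers validate strictly and raise :class:`FormatError` /
:class:`ValidationError` rather than coercing malformed input; every
reader/writer pair round-trips valid objects exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
DIAGNOSES = ("CTL", "AD")
METADATA_COLUMNS = ("sex", "diagnosis", "Age", "RIN", "PMI")


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns;
    row/column order is meaningful and preserved by I/O.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be finite integers")
        if np.any(values < 0):
            bad = df.index[np.any(values < 0, axis=1)].tolist()
            raise ValidationError(f"negative counts in genes: {bad[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.int64)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample phenotype table: sex, diagnosis, Age, RIN, PMI.

    ``table`` is indexed by sample id.  Missing PMI is represented as NaN
    (a true missing marker); imputation to a numeric sentinel is a pipeline
    stage, not an I/O concern.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex levels: {sorted(bad_sex)}")
        bad_dx = set(df["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ValidationError(f"unknown diagnosis levels: {sorted(bad_dx)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])

    def aligned_to(self, matrix: CountMatrix) -> "SampleMetadata":
        """Reindex to the matrix's sample order; every sample must be present."""
        absent = [s for s in matrix.sample_ids if s not in self.table.index]
        if absent:
            raise ValidationError(f"samples without metadata: {absent[:5]}")
        return self.subset(matrix.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene set names: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass(frozen=True)
class LiteratureCounts:
    """Pathway label -> (total mentions, co-mentions with the disease)."""

    counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (total, co) in self.counts.items():
            if total < 0 or co < 0:
                raise ValidationError(f"negative count for {label!r}")
            if co > total:
                raise ValidationError(
                    f"co-mentions ({co}) exceed total mentions ({total}) for {label!r}"
                )

    def __contains__(self, label: str) -> bool:
        return label in self.counts

    def __getitem__(self, label: str) -> tuple[int, int]:
        return self.counts[label]

    @property
    def labels(self) -> list[str]:
        return list(self.counts)


# ---------------------------------------------------------------------------
# count matrix TSV


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample TSV (first column gene id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count matrix contains non-numeric entries")
    values = values.astype(float)
    bad_rows = ~np.isfinite(values).all(axis=1)
    if bad_rows.any():
        raise FormatError(f"missing count in gene row {df.index[bad_rows][0]!r}")
    bad_rows = (values != np.floor(values)).any(axis=1)
    if bad_rows.any():
        raise FormatError(f"non-integer count in gene row {df.index[bad_rows][0]!r}")
    bad_rows = (values < 0).any(axis=1)
    if bad_rows.any():
        raise FormatError(f"negative count in gene row {df.index[bad_rows][0]!r}")
    try:
        return CountMatrix(df.astype(np.int64))
    except ValidationError as exc:  # duplicate ids
        raise FormatError(str(exc)) from exc


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata TSV


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample table; empty cells in numeric columns become missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("Age", "RIN", "PMI"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    try:
        return SampleMetadata(df)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB member...

    Duplicate member ids within a set are deduplicated (first occurrence
    wins) with a logged warning; a duplicate set *name* is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "gene set %r: %d duplicate member id(s) removed",
                    name,
                    len(members) - len(deduped),
                )
            sets.append(GeneSet(name, description, tuple(deduped)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            members = list(dict.fromkeys(s.members))
            fh.write("\t".join([s.name, s.description, *members]) + "\n")


# ---------------------------------------------------------------------------
# literature counts JSON


def read_literature_counts(path: str | Path) -> LiteratureCounts:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    counts: dict[str, tuple[int, int]] = {}
    for label, entry in raw.items():
        try:
            total = int(entry["total"])
            co = int(entry["co_mentions"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed literature entry for {label!r}") from exc
        counts[label] = (total, co)
    try:
        return LiteratureCounts(counts)
    except ValidationError as exc:
        raise type(exc)(str(exc)) from exc


def write_literature_counts(lit: LiteratureCounts, path: str | Path) -> None:
    payload = {
        label: {"total": total, "co_mentions": co}
        for label, (total, co) in lit.counts.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
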