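"""Reading and writing the tabular and genomic formats the pipeline touches.

The internal count model is a pandas DataFrame ("count table") with columns
``enhancer_id``, ``sample_id``, ``forward``, ``reverse`` — one row per
(enhancer, sample) pair, counts as non-negative integers. Genomic regions
use BED conventions throughout: 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import __version__

COUNT_COLUMNS = ["enhancer_id", "sample_id", "forward", "reverse"]


class CountTableFormatError(ValueError):
    """A count table violates the expected schema."""


class DuplicateKeyError(CountTableFormatError):
    """(enhancer_id, sample_id) pairs must be unique."""


class BedFormatError(ValueError):
    """A BED or bedGraph line could not be parsed."""


@dataclass(frozen=True)
class EnhancerRegion:
    """A candidate enhancer locus in BED coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    enhancer_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise BedFormatError(
                f"region {self.enhancer_id}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_count_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, dtypes and key uniqueness of a count table."""
    for col in COUNT_COLUMNS:
        if col not in df.columns:
            raise CountTableFormatError(f"missing required column: {col}")
    df = df[COUNT_COLUMNS].copy()
    for col in ("forward", "reverse"):
        values = df[col]
        numeric = pd.to_numeric(values, errors="coerce")
        if numeric.isna().any() or not np.allclose(numeric, np.round(numeric)):
            raise CountTableFormatError(f"column {col} must contain integers")
        if (numeric < 0).any():
            raise CountTableFormatError(f"column {col} contains negative counts")
        df[col] = numeric.astype(np.int64)
    dup = df.duplicated(subset=["enhancer_id", "sample_id"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["enhancer_id", "sample_id"]]
        raise DuplicateKeyError(
            f"duplicate (enhancer_id, sample_id) key: "
            f"({first['enhancer_id']}, {first['sample_id']})"
        )
    df["enhancer_id"] = df["enhancer_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    return df.reset_index(drop=True)


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (columns enhancer_id, sample_id, forward, reverse)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_count_table(df)


def write_count_table(df: pd.DataFrame, path, params: Mapping | None = None) -> None:
    """Write a count table as TSV with a ``#`` provenance header."""
    write_tsv(validate_count_table(df), path, params=params)


def write_tsv(df: pd.DataFrame, path, params: Mapping | None = None) -> None:
    """Write any result table as TSV, prefixed with tool version and parameters."""
    with open(path, "w") as handle:
        handle.write(f"# enhancerdir {__version__}\n")
        if params:
            rendered = " ".join(f"{k}={v}" for k, v in params.items())
            handle.write(f"# {rendered}\n")
        df.to_csv(handle, sep="\t", index=False)


def read_regions_bed(path) -> list[EnhancerRegion]:
    """Read enhancer regions from a BED3/BED4 file.

    Column 4 supplies the enhancer id when present; otherwise an id of the
    form ``chrom:start-end`` is synthesised.
    """
    regions: list[EnhancerRegion] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: expected at least 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedFormatError(
                    f"line {lineno}: start {start} must be < end {end}"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
                f"{chrom}:{start}-{end}"
            )
            if name in seen:
                raise BedFormatError(f"line {lineno}: duplicate enhancer id {name}")
            seen.add(name)
            regions.append(EnhancerRegion(chrom, start, end, name))
    return regions


def _read_bedgraph(path) -> Iterable[tuple[str, int, int, float, int]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(
                    f"{path} line {lineno}: expected 4 bedGraph columns"
                )
            try:
                yield fields[0], int(fields[1]), int(fields[2]), float(fields[3]), lineno
            except ValueError as exc:
                raise BedFormatError(
                    f"{path} line {lineno}: malformed bedGraph fields"
                ) from exc


def counts_from_bedgraph(
    plus, minus, regions: Sequence[EnhancerRegion], sample_id: str
) -> pd.DataFrame:
    """Aggregate strand-split bedGraph signal into a count table.

    Each bedGraph interval is assigned to the region containing its *start*
    position — in CTSS-style tracks the start is the 5' tag position, so a
    tag is counted once even when regions abut. Minus-strand values may be
    written as negative in the wild; the absolute value is taken.
    """
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region.enhancer_id
        )
    fwd = {r.enhancer_id: 0 for r in regions}
    rev = {r.enhancer_id: 0 for r in regions}
    for accumulator, path in ((fwd, plus), (rev, minus)):
        for chrom, start, _end, value, _lineno in _read_bedgraph(path):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.at(start):
                accumulator[hit.data] += int(round(abs(value)))
    table = pd.DataFrame(
        {
            "enhancer_id": [r.enhancer_id for r in regions],
            "sample_id": sample_id,
            "forward": [fwd[r.enhancer_id] for r in regions],
            "reverse": [rev[r.enhancer_id] for r in regions],
        }
    )
    return validate_count_table(table)


def read_group_map(path) -> pd.DataFrame:
    """Read a two-column cell-to-group mapping TSV (cell_id, group_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("cell_id", "group_id"):
        if col not in df.columns:
            raise CountTableFormatError(f"missing required column: {col}")
    if df["cell_id"].duplicated().any():
        raise DuplicateKeyError("cell_id values must be unique in a group mapping")
    return df[["cell_id", "group_id"]].reset_index(drop=True)


def read_label_table(path) -> pd.DataFrame:
    """Read an enhancer-label TSV (enhancer_id, label) for association tests."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("enhancer_id", "label"):
        if col not in df.columns:
            raise CountTableFormatError(f"missing required column: {col}")
    return df[["enhancer_id", "label"]].reset_index(drop=True)
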