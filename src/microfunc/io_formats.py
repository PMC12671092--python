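"""Readers and writers for the tab-separated table formats the tool touches.

Conventions
-----------
* Trait/GCN tables follow the PICRUSt2 layout on disk: one row per reference
  microbe, one column per gene family (microbes-as-rows). In memory the
  canonical orientation is functions x microbes so that ``A[i][k]`` is the
  copy number of function ``i`` in microbe ``k``.
* Abundance tables follow the classic BIOM-TSV layout: first header cell is
  conventionally ``#OTU ID``, remaining header cells are sample identifiers,
  one row per microbe.
* Numeric output uses Python's shortest round-trip ``repr`` (with a trailing
  ``.0`` stripped for integral values), so write-then-read is bit-stable.
* Gzip input is detected by magic bytes, never by file extension.
"""
from __future__ import annotations

import gzip
import io
import logging
from pathlib import Path
from typing import IO, Iterator, Literal, Union

import numpy as np
import pandas as pd

from .containers import (
    AbundanceTable,
    FunctionMicrobeMatrix,
    FunctionProfileMatrix,
    PathwayMap,
)
from .errors import ValidationError

logger = logging.getLogger("microfunc")

PathLike = Union[str, Path]

GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: PathLike) -> IO[str]:
    """Open a possibly gzip-compressed text file, sniffing magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _fmt(v: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    s = repr(float(v))
    return s[:-2] if s.endswith(".0") else s


def _read_numeric_frame(path: PathLike, what: str) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValidationError(f"{what} {path}: no data rows")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{what} {path}: duplicate row identifiers {dups[:10]}")
    if df.columns.duplicated().any():
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValidationError(f"{what} {path}: duplicate column identifiers {dups[:10]}")
    try:
        numeric = df.astype(np.float64)
    except (TypeError, ValueError):
        # locate the offending cell for a precise message
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValidationError(
                    f"{what} {path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise
    neg = numeric.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"{what} {path}: negative value at row {numeric.index[i]!r}, "
            f"column {numeric.columns[j]!r}"
        )
    return numeric


def read_gcn_table(
    path: PathLike,
    orientation: Literal["microbes-as-rows", "functions-as-rows"] = "microbes-as-rows",
) -> FunctionMicrobeMatrix:
    """Read a trait/GCN table into canonical functions x microbes orientation.

    Parameters
    ----------
    path:
        Tab-separated table (optionally gzip-compressed) with a header row.
    orientation:
        Layout of the file on disk. ``microbes-as-rows`` is the PICRUSt2
        trait-table convention and the default.
    """
    if orientation not in ("microbes-as-rows", "functions-as-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_numeric_frame(path, "GCN table")
    if orientation == "microbes-as-rows":
        df = df.T  # -> functions x microbes
    return FunctionMicrobeMatrix(
        list(df.index), list(df.columns), df.to_numpy(dtype=np.float64)
    )


def write_gcn_table(
    A: FunctionMicrobeMatrix,
    path: PathLike,
    orientation: Literal["microbes-as-rows", "functions-as-rows"] = "microbes-as-rows",
) -> None:
    """Write a GCN matrix as a tab-separated trait table."""
    if orientation == "microbes-as-rows":
        row_ids, col_ids = A.microbe_ids, A.function_ids
        values = A.values.T
        corner = "#microbe ID"
    else:
        row_ids, col_ids = A.function_ids, A.microbe_ids
        values = A.values
        corner = "#function ID"
    _write_table(path, corner, row_ids, col_ids, values)


def read_abundance_table(path: PathLike, drop_empty: bool = True) -> AbundanceTable:
    """Read a BIOM-style TSV abundance table (microbes x samples).

    ``drop_empty=True`` (default) removes all-zero sample columns with a log
    message; zero columns otherwise propagate to zero output columns.
    """
    df = _read_numeric_frame(path, "abundance table")
    table = AbundanceTable(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))
    if drop_empty:
        table = drop_empty_samples(table)
    return table


def drop_empty_samples(table: AbundanceTable) -> AbundanceTable:
    keep = table.values.sum(axis=0) > 0
    if keep.all():
        return table
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    logger.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped[:10])
    return AbundanceTable(
        list(table.microbe_ids),
        [s for s, k in zip(table.sample_ids, keep) if k],
        table.values[:, keep],
    )


def write_abundance_table(table: AbundanceTable, path: PathLike) -> None:
    _write_table(path, "#OTU ID", table.microbe_ids, table.sample_ids, table.values)


def read_function_profile(path: PathLike) -> FunctionProfileMatrix:
    """Read a functions x samples profile written by :func:`write_function_profile`."""
    df = _read_numeric_frame(path, "function profile")
    return FunctionProfileMatrix(list(df.index), list(df.columns), df.to_numpy())


def write_function_profile(C: FunctionProfileMatrix, path: PathLike) -> None:
    """Write the function x sample profile as TSV, preserving in-memory order."""
    if C.n_samples == 0:
        logger.warning("writing header-only profile: no samples")
    _write_table(path, "#function ID", C.function_ids, C.sample_ids, C.values)


def _write_table(path, corner: str, row_ids, col_ids, values) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([corner, *col_ids]) + "\n")
        for rid, row in zip(row_ids, np.atleast_2d(values)):
            fh.write("\t".join([rid, *(_fmt(v) for v in row)]) + "\n")


def read_pathway_map(path: PathLike) -> PathwayMap:
    """Read a two-column KO -> pathway TSV; repeated KO rows accumulate."""
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValidationError(
                    f"pathway map {path}: malformed line {lineno}: {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        logger.warning("pathway map %s is empty", path)
    return PathwayMap.from_pairs(pairs)


def write_pathway_map(pmap: PathwayMap, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ko in sorted(pmap.entries):
            for pw in sorted(pmap.entries[ko]):
                fh.write(f"{ko}\t{pw}\n")


def read_nsti_table(path: PathLike) -> dict[str, float]:
    """Read a two-column microbe -> NSTI distance TSV (header optional)."""
    out: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"NSTI table {path}: malformed line {lineno}")
            if lineno == 1 and fields[1].lower() in ("nsti", "distance", "d"):
                continue
            try:
                d = float(fields[1])
            except ValueError:
                raise ValidationError(
                    f"NSTI table {path}: non-numeric distance at line {lineno}"
                ) from None
            if d < 0:
                raise ValidationError(f"NSTI table {path}: negative distance at line {lineno}")
            if fields[0] in out:
                raise ValidationError(f"NSTI table {path}: duplicate id {fields[0]!r}")
            out[fields[0]] = d
    return out


def write_nsti_table(distances: dict[str, float], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#microbe ID\tNSTI\n")
        for mid, d in distances.items():
            fh.write(f"{mid}\t{_fmt(d)}\n")


def iter_abundance_chunks(
    path: PathLike, iteration_size: int, drop_empty: bool = False
) -> Iterator[AbundanceTable]:
    """Stream an on-disk abundance table in column chunks of <= iteration_size samples.

    Used by the memory-aware loading path: each chunk holds at most
    ``iteration_size`` samples; a resume cursor (sample offset) is logged after
    each chunk so an interrupted run can restart at an iteration boundary.
    """
    if iteration_size < 1:
        raise ValidationError("iteration_size must be >= 1")
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    n = len(sample_ids)
    start = 0
    while start < n:
        stop = min(start + iteration_size, n)
        with _open_text(path) as fh:
            df = pd.read_csv(
                fh, sep="\t", header=0, index_col=0,
                usecols=[0, *range(1 + start, 1 + stop)],
            )
        chunk = AbundanceTable(
            [str(i) for i in df.index],
            sample_ids[start:stop],
            df.to_numpy(dtype=np.float64),
        )
        if drop_empty:
            chunk = drop_empty_samples(chunk)
        logger.info("loaded samples [%d, %d) of %d (resume cursor: %d)", start, stop, n, stop)
        yield chunk
        start = stop
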