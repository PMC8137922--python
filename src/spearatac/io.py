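"""Readers and writers for the external formats the pipeline touches.

Dialects: FASTQ (plain or gzip), the 10x fragments TSV (chrom, start, end,
barcode, count; bgzip readable as gzip), MatrixMarket MTX with sidecar
row/column id files, BED3/BED6, and plain TSV tables for the sgRNA spacer
library and motif family annotations. Coordinates are uniformly 0-based
half-open, so BED requires no shifting.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.io import mmread, mmwrite

from spearatac.containers import FragmentRecord, IntervalSet, MotifMatchMatrix, SparseCountMatrix

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_SIZE = 500_000


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzip/bgzip text transparently (by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq_pair(
    spacer_path: str | Path,
    index_path: str | Path,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> Iterator[list[tuple[str, str]]]:
    """Stream lockstep (spacer sequence, barcode sequence) pairs in chunks.

    The spacer read (Read1) carries the sgRNA spacer at its start; the index
    read (Index1) carries the cell barcode. Records are paired positionally.
    Raises ``ValueError`` naming the shorter file on a record-count mismatch.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    with _open_text(spacer_path) as fh1, _open_text(index_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        chunk: list[tuple[str, str]] = []
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                shorter = spacer_path if r1 is None else index_path
                raise ValueError(
                    f"record count mismatch between FASTQ files: {shorter} is shorter"
                )
            chunk.append((r1[1], r2[1]))
            if len(chunk) >= chunk_size:
                yield chunk
                chunk = []
        if chunk:
            yield chunk


class FragmentReader:
    """Iterator over a fragments TSV that tracks skipped malformed lines.

    Lines with start >= end are skipped with a logged warning (``n_skipped``
    counts them); non-integer coordinates are a hard error. '#'-prefixed
    header lines are ignored. Barcode suffixes like "-1" are stripped when
    ``strip_suffix`` is set (whitelists omit the suffix).
    """

    def __init__(self, path: str | Path, strip_suffix: bool = True) -> None:
        self.path = Path(path)
        self.strip_suffix = strip_suffix
        self.n_skipped = 0

    def __iter__(self) -> Iterator[FragmentRecord]:
        with _open_text(self.path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{self.path}:{lineno}: expected >=4 columns")
                chrom, start_s, end_s, barcode = fields[:4]
                count = int(fields[4]) if len(fields) > 4 else 1
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ValueError(
                        f"{self.path}:{lineno}: non-integer coordinate"
                    ) from exc
                if start >= end:
                    self.n_skipped += 1
                    logger.warning(
                        "%s:%d: start >= end, skipped (%d so far)",
                        self.path, lineno, self.n_skipped,
                    )
                    continue
                if not barcode:
                    raise ValueError(f"{self.path}:{lineno}: empty barcode")
                if self.strip_suffix and "-" in barcode:
                    barcode = barcode.split("-", 1)[0]
                yield FragmentRecord(chrom, start, end, barcode, count)


def read_fragments(path: str | Path, strip_suffix: bool = True) -> FragmentReader:
    return FragmentReader(path, strip_suffix=strip_suffix)


def write_fragments(records, path: str | Path) -> int:
    n = 0
    with open(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")
            n += 1
    return n


def read_mtx(
    matrix_path: str | Path,
    row_path: str | Path,
    col_path: str | Path,
) -> SparseCountMatrix:
    """Read a MatrixMarket coordinate matrix with sidecar id files."""
    mat = mmread(str(matrix_path))
    rows = Path(row_path).read_text().splitlines()
    cols = Path(col_path).read_text().splitlines()
    return SparseCountMatrix(sp.csr_matrix(mat), rows, cols)


def write_mtx(
    counts: SparseCountMatrix,
    matrix_path: str | Path,
    row_path: str | Path,
    col_path: str | Path,
) -> None:
    mmwrite(str(matrix_path), counts.matrix.tocoo())
    Path(row_path).write_text("\n".join(counts.row_ids) + "\n")
    Path(col_path).write_text("\n".join(counts.col_ids) + "\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 (0-based half-open, as stored)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            row = {"chrom": fields[0], "start": int(fields[1]), "end": int(fields[2])}
            if len(fields) > 3:
                row["name"] = fields[3]
            rows.append(row)
    return IntervalSet(pd.DataFrame(rows))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in intervals.df.columns:
        cols.append("name")
    intervals.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_whitelist(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_spacer_library(path: str | Path) -> pd.DataFrame:
    """TSV with columns spacer, sgrna_id, target."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = {"spacer", "sgrna_id", "target"}
    if not req.issubset(df.columns):
        raise ValueError(f"spacer library requires columns {sorted(req)}")
    return df


def read_motif_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns motif_id, cluster."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"motif_id", "cluster"}.issubset(df.columns):
        raise ValueError("motif table requires columns motif_id, cluster")
    return df


def read_motif_matches(
    matrix_path: str | Path,
    motif_table_path: str | Path,
) -> MotifMatchMatrix:
    mat = sp.csc_matrix(mmread(str(matrix_path)) > 0)
    table = read_motif_table(motif_table_path)
    return MotifMatchMatrix(
        mat,
        table["motif_id"].tolist(),
        dict(zip(table["motif_id"], table["cluster"])),
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_gc_table(path: str | Path) -> pd.Series:
    """TSV peak_id -> GC fraction."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: float})
    if df.shape[1] < 2:
        raise ValueError("gc table requires two columns: peak id, gc fraction")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0])
    if np.any((s < 0) | (s > 1)):
        raise ValueError("gc fractions must lie in [0, 1]")
    return s
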