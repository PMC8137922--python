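"""In-memory containers shared across pipeline stages.

All genomic intervals are 0-based half-open. Count matrices are stored as
scipy CSR with explicit row (cell) and column (feature) identifier lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FragmentRecord(NamedTuple):
    """One Tn5-to-Tn5 accessible fragment with its cell barcode.

    Coordinates are 0-based half-open and assumed already Tn5-offset
    corrected (the 10x dialect emits +4/-5 adjusted positions). The two
    insertion sites are ``start`` and ``end - 1``.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1


@dataclass
class SparseCountMatrix:
    """Cells x features non-negative integer counts with id lists."""

    matrix: sp.csr_matrix
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if self.matrix.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match id lists "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row ids are not unique")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("column ids are not unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def col_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def subset_rows(self, ids: Sequence[str]) -> "SparseCountMatrix":
        idx = self.row_index()
        take = [idx[i] for i in ids]
        return SparseCountMatrix(self.matrix[take], list(ids), self.col_ids)

    def subset_cols(self, ids: Sequence[str]) -> "SparseCountMatrix":
        idx = {c: i for i, c in enumerate(self.col_ids)}
        take = [idx[i] for i in ids]
        return SparseCountMatrix(
            sp.csr_matrix(self.matrix.tocsc()[:, take]), self.row_ids, list(ids)
        )

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class IntervalSet:
    """Ordered genomic intervals, optionally with per-interval GC fraction.

    Intervals are 0-based half-open and must be sorted by start within each
    chromosome.
    """

    df: pd.DataFrame  # columns: chrom, start, end [, gc, name]

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        if not req.issubset(self.df.columns):
            raise ValueError(f"IntervalSet requires columns {sorted(req)}")
        df = self.df.reset_index(drop=True)
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ValueError("intervals must be sorted by start within chrom")
        if "gc" in df.columns:
            gc = df["gc"].to_numpy(dtype=float)
            if np.any((gc < 0) | (gc > 1)):
                raise ValueError("gc fractions must lie in [0, 1]")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def names(self) -> list[str]:
        if "name" in self.df.columns:
            return self.df["name"].astype(str).tolist()
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])
        ]

    def has_overlaps(self) -> bool:
        for _, sub in self.df.groupby("chrom", sort=False):
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            if len(sub) > 1 and np.any(starts[1:] < ends[:-1]):
                return True
        return False


@dataclass
class MotifMatchMatrix:
    """Peaks x motifs boolean match matrix plus the motif family table."""

    matches: sp.csc_matrix  # bool, peaks x motifs
    motif_ids: list[str]
    clusters: dict[str, str] = field(default_factory=dict)  # motif id -> family id

    def __post_init__(self) -> None:
        self.matches = sp.csc_matrix(self.matches, dtype=bool)
        self.motif_ids = list(self.motif_ids)
        if self.matches.shape[1] != len(self.motif_ids):
            raise ValueError("motif id count does not match matrix columns")
        if self.clusters:
            missing = set(self.motif_ids) - set(self.clusters)
            if missing:
                raise ValueError(f"motifs missing from cluster table: {sorted(missing)[:5]}")
            if any(not c for c in self.clusters.values()):
                raise ValueError("cluster ids must be non-empty")

    @property
    def n_peaks(self) -> int:
        return self.matches.shape[0]

    @property
    def n_motifs(self) -> int:
        return self.matches.shape[1]

    def peaks_for(self, motif_id: str) -> np.ndarray:
        j = self.motif_ids.index(motif_id)
        return self.matches[:, j].nonzero()[0]
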