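"""sgRNA spacer demultiplexing and per-cell assignment.

Reads from the targeted sgRNA-enrichment library carry the spacer at the
start of Read1 and the cell barcode in the index read. Barcodes resolve
against a whitelist allowing at most one mismatch (ambiguous queries are
discarded); spacers match the library exactly, anchored at the read start
with an optional small scan window. A cell receives a high-fidelity
assignment when it has at least ``min_counts`` total sgRNA reads and the
top sgRNA accounts for at least ``min_specificity`` of them — the
20-count / 0.8-specificity rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp

from spearatac.containers import SparseCountMatrix

_BASES = "ACGT"
AMBIGUOUS = "__ambiguous__"


class BarcodeIndex:
    """Whitelist lookup resolving queries within Hamming distance 1.

    Exact matches always win. A query at distance 1 from two or more
    whitelist entries (and not itself a whitelist entry) is ambiguous and
    resolves to None.
    """

    def __init__(self, whitelist: Iterable[str]) -> None:
        whitelist = list(whitelist)
        if not whitelist:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in whitelist}
        if len(lengths) != 1:
            raise ValueError("whitelist barcodes must share one length")
        self.barcode_length = lengths.pop()
        self.whitelist = whitelist
        self._exact = set(whitelist)
        if len(self._exact) != len(whitelist):
            raise ValueError("duplicate whitelist barcodes")
        # one-mismatch variants; collisions between different barcodes mark
        # the variant ambiguous
        self._one_mm: dict[str, str] = {}
        for bc in whitelist:
            for i in range(self.barcode_length):
                for base in _BASES + "N":
                    if base == bc[i]:
                        continue
                    var = bc[:i] + base + bc[i + 1 :]
                    if var in self._one_mm and self._one_mm[var] != bc:
                        self._one_mm[var] = AMBIGUOUS
                    else:
                        self._one_mm[var] = bc

    def resolve(self, query: str) -> str | None:
        """Return the whitelist barcode for ``query``, or None."""
        if query in self._exact:
            return query
        hit = self._one_mm.get(query)
        if hit is None or hit == AMBIGUOUS:
            return None
        return hit

    def is_ambiguous(self, query: str) -> bool:
        return query not in self._exact and self._one_mm.get(query) == AMBIGUOUS


class SpacerLibrary:
    """sgRNA spacer dictionary: spacer sequence -> sgRNA id -> target gene."""

    def __init__(self, table: pd.DataFrame) -> None:
        req = {"spacer", "sgrna_id", "target"}
        if not req.issubset(table.columns):
            raise ValueError(f"spacer library requires columns {sorted(req)}")
        if table["spacer"].duplicated().any():
            raise ValueError("spacer sequences must be unique")
        if table.groupby("sgrna_id")["target"].nunique().max() > 1:
            raise ValueError("each sgRNA id must map to exactly one target")
        lengths = table["spacer"].str.len().unique()
        if len(lengths) != 1:
            raise ValueError("spacers must share one length")
        self.spacer_length = int(lengths[0])
        self.table = table.reset_index(drop=True)
        self._by_spacer = dict(zip(table["spacer"], table["sgrna_id"]))
        self.targets = dict(zip(table["sgrna_id"], table["target"]))
        self.sgrna_ids = table["sgrna_id"].tolist()

    def lookup(self, read: str, scan_window: int = 0) -> str | None:
        """Exact spacer match anchored at position 0, scanning up to
        ``scan_window`` leading bases."""
        L = self.spacer_length
        for off in range(scan_window + 1):
            hit = self._by_spacer.get(read[off : off + L])
            if hit is not None:
                return hit
        return None


def match_read(
    spacer_read: str,
    barcode_read: str,
    index: BarcodeIndex,
    library: SpacerLibrary,
    scan_window: int = 0,
) -> tuple[str | None, str | None]:
    """Resolve one read pair to (cell barcode, sgRNA id); None where unresolved."""
    cell = index.resolve(barcode_read[: index.barcode_length])
    sgrna = library.lookup(spacer_read, scan_window=scan_window)
    return cell, sgrna


@dataclass
class MatchReport:
    """Per-run demultiplexing totals."""

    n_reads: int = 0
    n_barcode_matched: int = 0
    n_spacer_matched: int = 0
    n_both_matched: int = 0
    n_barcode_ambiguous: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def build_count_matrix(
    chunks: Iterator[list[tuple[str, str]]],
    index: BarcodeIndex,
    library: SpacerLibrary,
    scan_window: int = 0,
) -> tuple[SparseCountMatrix, MatchReport]:
    """Accumulate the cells x sgRNAs read-count matrix from streamed pairs.

    Entry (c, g) counts read pairs whose barcode resolved to cell c and
    whose spacer matched sgRNA g. The matrix grand total equals the
    "both matched" total in the report.
    """
    report = MatchReport()
    counts: dict[tuple[str, str], int] = {}
    bl = index.barcode_length
    for chunk in chunks:
        for spacer_read, barcode_read in chunk:
            report.n_reads += 1
            cell = index.resolve(barcode_read[:bl])
            if cell is None and index.is_ambiguous(barcode_read[:bl]):
                report.n_barcode_ambiguous += 1
            sgrna = library.lookup(spacer_read, scan_window=scan_window)
            if cell is not None:
                report.n_barcode_matched += 1
            if sgrna is not None:
                report.n_spacer_matched += 1
            if cell is not None and sgrna is not None:
                report.n_both_matched += 1
                counts[(cell, sgrna)] = counts.get((cell, sgrna), 0) + 1

    cells = sorted({c for c, _ in counts})
    sgrnas = library.sgrna_ids
    cell_idx = {c: i for i, c in enumerate(cells)}
    sg_idx = {g: j for j, g in enumerate(sgrnas)}
    if counts:
        rows, cols, data = zip(
            *((cell_idx[c], sg_idx[g], n) for (c, g), n in counts.items())
        )
        mat = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(cells), len(sgrnas)), dtype=np.int64
        ).tocsr()
    else:
        mat = sp.csr_matrix((0, len(sgrnas)), dtype=np.int64)
    return SparseCountMatrix(mat, cells, sgrnas), report


def assign_cells(
    counts: SparseCountMatrix,
    library: SpacerLibrary,
    min_counts: int = 20,
    min_specificity: float = 0.8,
    by_target: bool = False,
) -> pd.DataFrame:
    """Call one sgRNA (and its target) per cell from the count matrix.

    A cell is assigned to its top-count sgRNA iff its total sgRNA reads
    reach ``min_counts`` and specificity (top / total) reaches
    ``min_specificity``; otherwise it is unassigned with a reason among
    low_counts, low_specificity, tie. With ``by_target`` the counts of
    sgRNAs sharing a target are summed before the ratio (the looser,
    gene-level reading).

    Returns a DataFrame indexed by cell with columns sgrna, target,
    n_counts, specificity, assigned, reason.
    """
    dense = counts.to_dense().astype(np.int64)
    col_ids = counts.col_ids
    col_targets = [library.targets[g] for g in col_ids]

    if by_target:
        targets = sorted(set(col_targets))
        t_idx = {t: j for j, t in enumerate(targets)}
        agg = np.zeros((dense.shape[0], len(targets)), dtype=np.int64)
        for j, t in enumerate(col_targets):
            agg[:, t_idx[t]] += dense[:, j]
        score_mat, score_ids = agg, targets
    else:
        score_mat, score_ids = dense, col_ids

    rows = []
    totals = dense.sum(axis=1)
    for i, cell in enumerate(counts.row_ids):
        total = int(totals[i])
        if total == 0:
            rows.append((cell, None, None, 0, np.nan, False, "low_counts"))
            continue
        top_j = int(np.argmax(score_mat[i]))
        c_top = int(score_mat[i, top_j])
        spec = c_top / total
        n_at_top = int(np.sum(score_mat[i] == c_top))
        if total < min_counts:
            rows.append((cell, None, None, total, spec, False, "low_counts"))
        elif n_at_top > 1:
            rows.append((cell, None, None, total, spec, False, "tie"))
        elif spec < min_specificity:
            rows.append((cell, None, None, total, spec, False, "low_specificity"))
        else:
            if by_target:
                target = score_ids[top_j]
                sub = [j for j, t in enumerate(col_targets) if t == target]
                sg = col_ids[sub[int(np.argmax(dense[i, sub]))]]
            else:
                sg = score_ids[top_j]
                target = library.targets[sg]
            rows.append((cell, sg, target, total, spec, True, ""))

    return pd.DataFrame(
        rows,
        columns=["cell", "sgrna", "target", "n_counts", "specificity", "assigned", "reason"],
    ).set_index("cell")


def assignment_summary(assignments: pd.DataFrame, n_captured: int) -> dict:
    """Summarize assignment yield against the number of captured nuclei."""
    if n_captured <= 0:
        raise ValueError("n_captured must be positive")
    assigned = assignments[assignments["assigned"].astype(bool)]
    n_assigned = int(len(assigned))
    if n_assigned > n_captured:
        raise ValueError("more assigned cells than captured nuclei")
    per_target = assigned["target"].value_counts().to_dict()
    fraction = n_assigned / n_captured
    return {
        "n_assigned": n_assigned,
        "n_captured": n_captured,
        "fraction_assigned": fraction,
        "percent_assigned": round(100.0 * fraction),
        "per_target": per_target,
    }


def cost_per_cell(cost_per_sample: float, n_dual_readout_cells: int) -> float:
    """Cost per cell with both accessibility and sgRNA read-outs, in
    currency rounded to cents."""
    if n_dual_readout_cells <= 0:
        raise ValueError("n_dual_readout_cells must be positive")
    return round(cost_per_sample / n_dual_readout_cells, 2)
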