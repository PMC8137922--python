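"""Assignment refinement by neighborhood purity.

For each target, the target's cells and the non-targeting cells are
re-embedded (LSI) on the tiles most reproducibly differential between the
target and the controls; each target cell's PurityRatio is the fraction of
its k nearest neighbors (cosine distance) that are also assigned to the
target. Cells keep their assignment only when the ratio exceeds the
threshold (default 0.9, k = 20) — misassigned cells sit among control
cells in this space and fail the cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from spearatac.containers import SparseCountMatrix
from spearatac.matrices import lsi_embed, pseudobulk


def reproducible_diff_tiles(
    tiles: SparseCountMatrix,
    assignments: pd.DataFrame,
    target: str,
    nt_label: str = "NT",
    n_each: int = 5000,
    scale_to: float = 1e6,
) -> list[str]:
    """Top differential tiles between a target and non-targeting cells,
    kept only when reproducible across the target's individual sgRNAs.

    Fold changes are log2 of scaled pseudobulk profiles with pseudocount 1.
    A tile is reproducible when the sign of its target-vs-NT log2FC agrees
    for every individual sgRNA of the target. The top ``n_each`` increasing
    and ``n_each`` decreasing reproducible tiles are returned (fewer if not
    available). Ordering is deterministic: ties broken by absolute scaled
    difference, then tile id.
    """
    assigned = assignments[assignments["assigned"]]
    t_cells = assigned.index[assigned["target"] == target]
    nt_cells = assigned.index[assigned["target"] == nt_label]
    if len(t_cells) == 0 or len(nt_cells) == 0:
        raise ValueError("need both target and non-targeting cells")

    groups = {c: "target" for c in t_cells}
    groups.update({c: "nt" for c in nt_cells})
    pb = pseudobulk(tiles, groups, scale_to=scale_to)
    lfc = np.log2(pb["target"] + 1.0) - np.log2(pb["nt"] + 1.0)
    absdiff = (pb["target"] - pb["nt"]).abs()

    sgrnas = assigned.loc[t_cells, "sgrna"].unique()
    sign_ok = np.ones(len(lfc), dtype=bool)
    for sg in sgrnas:
        sg_cells = assigned.index[(assigned["sgrna"] == sg)]
        g = {c: "sg" for c in sg_cells}
        g.update({c: "nt" for c in nt_cells})
        pb_sg = pseudobulk(tiles, g, scale_to=scale_to)
        lfc_sg = np.log2(pb_sg["sg"] + 1.0) - np.log2(pb_sg["nt"] + 1.0)
        sign_ok &= np.sign(lfc_sg.to_numpy()) == np.sign(lfc.to_numpy())

    frame = pd.DataFrame(
        {"lfc": lfc, "absdiff": absdiff}, index=pb.index
    )[sign_ok]
    up = frame[frame["lfc"] > 0]
    down = frame[frame["lfc"] < 0]
    # stable sort on tile id first so equal (lfc, absdiff) order deterministically
    up = up.sort_index(kind="mergesort").sort_values(
        ["lfc", "absdiff"], ascending=[False, False], kind="mergesort"
    )
    down = down.sort_index(kind="mergesort").sort_values(
        ["lfc", "absdiff"], ascending=[True, False], kind="mergesort"
    )
    return up.index[:n_each].tolist() + down.index[:n_each].tolist()


@dataclass
class PurityResult:
    """Per-cell neighborhood purity for one target."""

    table: pd.DataFrame  # index: cell; columns purity_ratio, kept
    target: str
    k_used: int
    threshold: float


def purity_ratio(
    tiles: SparseCountMatrix,
    assignments: pd.DataFrame,
    target: str,
    selected_tiles: list[str],
    nt_label: str = "NT",
    k: int = 20,
    n_dims: int = 30,
    threshold: float = 0.9,
    seed: int = 0,
) -> PurityResult:
    """Compute PurityRatio for each of a target's cells.

    The target's cells plus the non-targeting cells are LSI-embedded on
    ``selected_tiles``; purity is the fraction of each target cell's k
    nearest neighbors (cosine, excluding self) assigned to the target.
    Kept iff purity_ratio > threshold (strict).
    """
    assigned = assignments[assignments["assigned"]]
    t_cells = assigned.index[assigned["target"] == target].tolist()
    nt_cells = assigned.index[assigned["target"] == nt_label].tolist()
    cells = t_cells + nt_cells
    if len(cells) < 2:
        raise ValueError("need at least 2 cells for neighbor analysis")

    sub = tiles.subset_rows(cells).subset_cols(selected_tiles)
    emb = lsi_embed(sub, n_dims=n_dims, top_features=None, seed=seed)
    coords = emb.coords

    k_used = min(k, len(cells) - 1)
    nn = NearestNeighbors(n_neighbors=k_used + 1, metric="cosine")
    nn.fit(coords)
    is_target = np.array([c in set(t_cells) for c in cells])
    t_idx = np.where(is_target)[0]
    _, neigh = nn.kneighbors(coords[t_idx])
    ratios = np.empty(len(t_idx))
    for r, (i, row) in enumerate(zip(t_idx, neigh)):
        others = row[row != i][:k_used]
        ratios[r] = is_target[others].mean()
    table = pd.DataFrame(
        {"purity_ratio": ratios, "kept": ratios > threshold},
        index=pd.Index(t_cells, name="cell"),
    )
    return PurityResult(table=table, target=target, k_used=k_used, threshold=threshold)


def refine_assignments(
    assignments: pd.DataFrame, purities: list[PurityResult]
) -> pd.DataFrame:
    """Drop assignments whose PurityRatio failed the threshold.

    Non-targeting cells are never filtered. Returns a copy with failing
    cells marked unassigned (reason "low_purity").
    """
    out = assignments.copy()
    for col in ("sgrna", "target", "reason"):
        out[col] = out[col].astype(object)
    out["assigned"] = out["assigned"].astype(bool)
    for pr in purities:
        dropped = pr.table.index[~pr.table["kept"]]
        out.loc[dropped, "assigned"] = False
        out.loc[dropped, "reason"] = "low_purity"
        out.loc[dropped, "sgrna"] = None
        out.loc[dropped, "target"] = None
    return out
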