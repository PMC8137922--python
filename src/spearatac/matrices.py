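"""Tile/peak count matrices, per-cell QC, pseudobulk profiles, and LSI.

Each fragment contributes exactly two Tn5 insertion events, at positions
``start`` and ``end - 1`` (coordinates already offset-corrected upstream).
Tile and peak matrices count insertions per cell; per-cell quality is
summarized by fragment count and TSS enrichment. LSI is TF-IDF weighting
of the binarized matrix followed by truncated SVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from spearatac.containers import FragmentRecord, IntervalSet, SparseCountMatrix

logger = logging.getLogger(__name__)


def _collect_insertions(
    fragments: Iterable[FragmentRecord],
) -> tuple[list[str], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Gather insertion sites grouped by chromosome.

    Returns (cell ids in first-seen order, {chrom: (cell indices, positions)}).
    """
    cells: dict[str, int] = {}
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for frag in fragments:
        ci = cells.setdefault(frag.barcode, len(cells))
        idxs, poss = by_chrom.setdefault(frag.chrom, ([], []))
        idxs.append(ci)
        poss.append(frag.start)
        idxs.append(ci)
        poss.append(frag.end - 1)
    out = {
        chrom: (np.asarray(i, dtype=np.int64), np.asarray(p, dtype=np.int64))
        for chrom, (i, p) in by_chrom.items()
    }
    return list(cells), out


def make_tile_matrix(
    fragments: Iterable[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    tile_size: int = 500,
) -> SparseCountMatrix:
    """Cells x fixed-width genome tiles insertion-count matrix.

    Tile index within a chromosome is floor(position / tile_size).
    Insertions beyond the chromosome end are clipped into the last tile
    with a warning. Chromosomes absent from ``chrom_sizes`` are an error.
    """
    cell_ids, by_chrom = _collect_insertions(fragments)
    unknown = set(by_chrom) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on chromosomes missing from chrom_sizes: {sorted(unknown)}")

    tile_ids: list[str] = []
    offsets: dict[str, int] = {}
    n_tiles_per: dict[str, int] = {}
    for chrom, size in chrom_sizes.items():
        n_tiles = int(np.ceil(size / tile_size))
        offsets[chrom] = len(tile_ids)
        n_tiles_per[chrom] = n_tiles
        tile_ids.extend(
            f"{chrom}:{t * tile_size}-{min((t + 1) * tile_size, size)}"
            for t in range(n_tiles)
        )

    rows, cols = [], []
    for chrom, (cells, pos) in by_chrom.items():
        n_tiles = n_tiles_per[chrom]
        tiles = pos // tile_size
        n_clip = int(np.sum(tiles >= n_tiles))
        if n_clip:
            logger.warning("%d insertions beyond %s end; clipped", n_clip, chrom)
            tiles = np.minimum(tiles, n_tiles - 1)
        tiles = np.maximum(tiles, 0)
        rows.append(cells)
        cols.append(tiles + offsets[chrom])

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        mat = sp.coo_matrix(
            (np.ones(len(r), dtype=np.int64), (r, c)),
            shape=(len(cell_ids), len(tile_ids)),
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(cell_ids), len(tile_ids)), dtype=np.int64)
    return SparseCountMatrix(mat, cell_ids, tile_ids)


def make_peak_matrix(
    fragments: Iterable[FragmentRecord],
    peaks: IntervalSet,
) -> SparseCountMatrix:
    """Cells x peaks insertion counts over half-open peak intervals.

    Peaks must be sorted and non-overlapping; a fragment spanning two peaks
    contributes one insertion to each. Insertions outside every peak are
    ignored.
    """
    if peaks.has_overlaps():
        raise ValueError("peaks must be non-overlapping")
    cell_ids, by_chrom = _collect_insertions(fragments)
    peak_ids = peaks.names()

    rows, cols = [], []
    pdf = peaks.df.reset_index(drop=True)
    pdf["_j"] = np.arange(len(pdf))
    for chrom, sub in pdf.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        cells, pos = by_chrom[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        glob = sub["_j"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.maximum(k, 0)])
        rows.append(cells[ok])
        cols.append(glob[k[ok]])

    if rows and sum(len(r) for r in rows):
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        mat = sp.coo_matrix(
            (np.ones(len(r), dtype=np.int64), (r, c)),
            shape=(len(cell_ids), len(peak_ids)),
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(cell_ids), len(peak_ids)), dtype=np.int64)
    return SparseCountMatrix(mat, cell_ids, peak_ids)


def compute_qc(
    fragments: Iterable[FragmentRecord],
    tss: IntervalSet,
    center_halfwidth: int = 50,
    flank_inner: int = 1901,
    flank_outer: int = 2000,
) -> pd.DataFrame:
    """Per-cell fragment counts and TSS enrichment.

    TSS enrichment is the per-bp insertion rate within +/-``center_halfwidth``
    bp of the nearest TSS divided by the per-bp rate in the two distal flanks
    ``flank_inner``..``flank_outer`` bp away, with a +1 pseudocount on the
    flank insertion total. A cell with no signal anywhere scores 0.
    """
    frag_list = list(fragments)
    n_frags: dict[str, int] = {}
    for f in frag_list:
        n_frags[f.barcode] = n_frags.get(f.barcode, 0) + 1
    cell_ids, by_chrom = _collect_insertions(frag_list)

    tss_by_chrom = {
        chrom: np.sort(sub["start"].to_numpy())
        for chrom, sub in tss.df.groupby("chrom", sort=False)
    }
    center = np.zeros(len(cell_ids), dtype=np.int64)
    flank = np.zeros(len(cell_ids), dtype=np.int64)
    for chrom, (cells, pos) in by_chrom.items():
        sites = tss_by_chrom.get(chrom)
        if sites is None or len(sites) == 0:
            continue
        j = np.searchsorted(sites, pos)
        left = sites[np.maximum(j - 1, 0)]
        right = sites[np.minimum(j, len(sites) - 1)]
        dist = np.minimum(np.abs(pos - left), np.abs(pos - right))
        np.add.at(center, cells, (dist <= center_halfwidth).astype(np.int64))
        in_flank = (dist >= flank_inner) & (dist <= flank_outer)
        np.add.at(flank, cells, in_flank.astype(np.int64))

    center_bp = 2 * center_halfwidth + 1
    flank_bp = 2 * (flank_outer - flank_inner + 1)
    center_rate = center / center_bp
    flank_rate = (flank + 1) / flank_bp
    enrich = np.where(center == 0, 0.0, center_rate / flank_rate)
    return pd.DataFrame(
        {
            "n_fragments": [n_frags[c] for c in cell_ids],
            "tss_enrichment": enrich,
        },
        index=pd.Index(cell_ids, name="cell"),
    )


def filter_cells(
    qc: pd.DataFrame, min_tss: float = 4.0, min_frags: int = 1000
) -> list[str]:
    """Cells passing both QC thresholds (TSS enrichment and fragment count)."""
    keep = (qc["tss_enrichment"] >= min_tss) & (qc["n_fragments"] >= min_frags)
    return qc.index[keep].tolist()


def pseudobulk(
    counts: SparseCountMatrix,
    groups: Mapping[str, str] | pd.Series,
    scale_to: float = 1e6,
) -> pd.DataFrame:
    """Per-group summed counts rescaled to a fixed column total.

    Returns features x groups; each non-empty group column sums to
    ``scale_to``. Empty groups give zero columns with a warning.
    """
    groups = dict(groups)
    ridx = counts.row_index()
    missing = set(groups) - set(ridx)
    if missing:
        raise ValueError(f"grouped cells missing from counts: {sorted(missing)[:5]}")
    names = sorted(set(groups.values()))
    out = np.zeros((len(counts.col_ids), len(names)))
    for j, name in enumerate(names):
        members = [ridx[c] for c, g in groups.items() if g == name]
        col = np.asarray(counts.matrix[members].sum(axis=0)).ravel().astype(float)
        total = col.sum()
        if total == 0:
            logger.warning("pseudobulk group %r has zero counts", name)
        else:
            col = col * (scale_to / total)
        out[:, j] = col
    return pd.DataFrame(out, index=counts.col_ids, columns=names)


@dataclass
class LSIEmbedding:
    """Latent semantic indexing of the binarized accessibility matrix."""

    coords: np.ndarray  # cells x d, U * s
    singular_values: np.ndarray
    components: np.ndarray  # d x features (V^T)
    feature_ids: list[str]
    cell_ids: list[str]
    depth_correlation: np.ndarray  # |corr| of each component with log10 depth
    flagged_components: np.ndarray  # depth-correlated (|r| > 0.75)


def lsi_embed(
    counts: SparseCountMatrix,
    n_dims: int = 30,
    top_features: int | None = 25_000,
    scale_factor: float = 1e4,
    depth_corr_cutoff: float = 0.75,
    drop_depth_correlated: bool = False,
    seed: int = 0,
) -> LSIEmbedding:
    """TF-IDF + truncated SVD embedding of binarized counts.

    Counts are binarized; term frequency is each entry over its cell total,
    scaled as log(1 + tf * scale_factor); inverse document frequency is
    log(1 + n_cells / (1 + feature frequency)). Components whose absolute
    Pearson correlation with log10 cell depth exceeds the cutoff are
    flagged (and dropped from ``coords`` only when requested).
    """
    n_cells = counts.shape[0]
    if n_cells < 2:
        raise ValueError("LSI requires at least 2 cells")
    depth = counts.row_totals().astype(float)

    X = counts.matrix
    if top_features is not None and X.shape[1] > top_features:
        totals = counts.col_totals()
        order = np.argsort(totals)[::-1]
        keep = np.sort(order[:top_features])
    else:
        keep = np.arange(X.shape[1])
    B = (X.tocsc()[:, keep] > 0).astype(float).tocsr()
    freq = np.asarray(B.sum(axis=0)).ravel()
    nonzero = freq > 0
    keep = keep[nonzero]
    B = B.tocsc()[:, nonzero].tocsr()
    freq = freq[nonzero]
    feature_ids = [counts.col_ids[j] for j in keep]

    cell_tot = np.asarray(B.sum(axis=1)).ravel()
    if np.any(cell_tot == 0):
        raise ValueError("cells with zero accessible features cannot be embedded")
    tf = sp.diags(1.0 / cell_tot) @ B
    tf.data = np.log1p(tf.data * scale_factor)
    idf = np.log1p(n_cells / (1.0 + freq))
    tfidf = (tf @ sp.diags(idf)).tocsr()

    k = min(n_dims, min(tfidf.shape) - 1)
    if k < 1:
        raise ValueError("matrix too small for the requested dimensionality")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(tfidf.shape))
    u, s, vt = svds(tfidf, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    # deterministic sign convention: largest-|.| loading positive
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u * s

    logd = np.log10(np.maximum(depth, 1.0))
    if np.std(logd) == 0:
        corr = np.zeros(k)
    else:
        corr = np.array(
            [
                0.0 if np.std(coords[:, i]) == 0
                else abs(np.corrcoef(coords[:, i], logd)[0, 1])
                for i in range(k)
            ]
        )
    flagged = corr > depth_corr_cutoff
    if drop_depth_correlated and flagged.any():
        keep_c = ~flagged
        coords, s, vt = coords[:, keep_c], s[keep_c], vt[keep_c]
        corr, flagged = corr[keep_c], flagged[keep_c]
    return LSIEmbedding(
        coords=coords,
        singular_values=s,
        components=vt,
        feature_ids=feature_ids,
        cell_ids=list(counts.row_ids),
        depth_correlation=corr,
        flagged_components=flagged,
    )


def umap_embed(
    embedding: LSIEmbedding,
    n_neighbors: int = 40,
    min_dist: float = 0.4,
    metric: str = "cosine",
    seed: int = 0,
) -> pd.DataFrame:
    """2-D UMAP of an LSI embedding, for visualization only.

    Neighborhood-based computations (e.g. purity filtering) use the LSI
    space directly; 2-D projections distort neighborhoods.
    """
    import umap

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, metric=metric, random_state=seed
    )
    coords = reducer.fit_transform(embedding.coords)
    return pd.DataFrame(coords, index=embedding.cell_ids, columns=["UMAP1", "UMAP2"])


def pseudobulk_pca(pb: pd.DataFrame, n_dims: int = 10) -> pd.DataFrame:
    """Principal components of log2(scaled + 1) pseudobulk group profiles.

    Used for manual review of non-targeting outlier sgRNAs; exclusion
    itself is a configuration choice, not automated.
    """
    if pb.shape[1] < 2:
        raise ValueError("pseudobulk PCA requires at least 2 groups")
    logmat = np.log2(pb.to_numpy().T + 1.0)  # groups x features
    centered = logmat - logmat.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_dims, len(s))
    # deterministic sign convention
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u[:, :k] * s[:k]
    return pd.DataFrame(
        coords, index=pb.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
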