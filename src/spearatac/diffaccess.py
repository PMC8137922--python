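"""Peak-level differential accessibility and downstream peak-set analyses.

The per-peak test is an exact binomial: the target group's counts at a
peak against the background group's smoothed per-peak proportion. Fold
changes come from scaled pseudobulk profiles with a pseudocount of 1.
Selected peaks feed k-means z-score modules (heatmap rows) and an
upper-tail hypergeometric motif enrichment against all tested peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from spearatac.containers import MotifMatchMatrix, SparseCountMatrix
from spearatac.matrices import pseudobulk


def binomial_diff_peaks(
    counts: SparseCountMatrix,
    target_cells: list[str],
    background_cells: list[str],
    scale_to: float = 1e6,
) -> pd.DataFrame:
    """Exact binomial test of each peak's target counts vs background rate.

    For peak p: k = summed target counts at p, n = total target counts,
    p0 = (background counts at p + 1) / (background total + n_peaks)
    (add-one smoothing so p0 > 0); two-sided exact binomial p-value.
    log2FC is computed from scaled pseudobulk with pseudocount 1; FDR is
    Benjamini-Hochberg across peaks.
    """
    if len(target_cells) < 2 or len(background_cells) < 2:
        raise ValueError("need at least 2 cells per group")
    tmat = counts.subset_rows(target_cells)
    bmat = counts.subset_rows(background_cells)
    tk = tmat.col_totals().astype(np.int64)
    bk = bmat.col_totals().astype(np.int64)
    n = int(tk.sum())
    b_total = int(bk.sum())
    if b_total == 0:
        raise ValueError("background group has zero counts")
    n_peaks = counts.shape[1]
    p0 = (bk + 1.0) / (b_total + n_peaks)

    pvals = np.array(
        [binomtest(int(k), n, p).pvalue if n > 0 else 1.0 for k, p in zip(tk, p0)]
    )
    groups = {c: "target" for c in target_cells}
    groups.update({c: "background" for c in background_cells})
    pb = pseudobulk(counts, groups, scale_to=scale_to)
    lfc = (np.log2(pb["target"] + 1.0) - np.log2(pb["background"] + 1.0)).to_numpy()
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": np.sign(lfc).astype(int),
            "target_counts": tk,
            "background_counts": bk,
        },
        index=pd.Index(counts.col_ids, name="peak"),
    )


@dataclass
class DifferentialPeaks:
    """Thresholded differential peak sets with yield fractions."""

    up: list[str]
    down: list[str]
    n_tested: int

    @property
    def fraction_up(self) -> float:
        return len(self.up) / self.n_tested

    @property
    def fraction_down(self) -> float:
        return len(self.down) / self.n_tested


def filter_differential(
    diff: pd.DataFrame, min_abs_lfc: float = 0.5, max_fdr: float = 0.1
) -> DifferentialPeaks:
    """Split peaks into significant up/down sets by |log2FC| and FDR."""
    up = diff.index[(diff["log2fc"] > min_abs_lfc) & (diff["fdr"] < max_fdr)]
    down = diff.index[(diff["log2fc"] < -min_abs_lfc) & (diff["fdr"] < max_fdr)]
    return DifferentialPeaks(up=up.tolist(), down=down.tolist(), n_tested=len(diff))


def timecourse_union_filter(
    diffs: list[pd.DataFrame],
    union_lfc: float = 1.0,
    keep_lfc: float = 0.25,
    max_fdr: float = 0.1,
) -> list[str]:
    """Union of strongly differential peaks across timepoints, re-filtered.

    A peak enters through any timepoint with |log2FC| > ``union_lfc`` (and
    FDR below ``max_fdr``), then survives only if some timepoint shows
    |log2FC| > ``keep_lfc``.
    """
    if not diffs:
        raise ValueError("need at least one timepoint")
    union: set[str] = set()
    for d in diffs:
        sel = d.index[(d["log2fc"].abs() > union_lfc) & (d["fdr"] < max_fdr)]
        union.update(sel)
    kept = [
        p
        for p in sorted(union)
        if any(abs(d.loc[p, "log2fc"]) > keep_lfc for d in diffs if p in d.index)
    ]
    return kept


def kmeans_peak_modules(
    pb: pd.DataFrame,
    peak_set: list[str],
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.Series, pd.DataFrame]:
    """k-means modules of z-scored log2 pseudobulk peak profiles.

    Rows are log2(scaled + 1) per peak, z-scored across groups; constant
    rows (undefined z) are dropped. Best of ``n_restarts`` seeded runs by
    inertia. Returns (peak -> module labels 1..k, the z-scored matrix).
    """
    sub = pb.loc[peak_set]
    logm = np.log2(sub.to_numpy() + 1.0)
    mu = logm.mean(axis=1, keepdims=True)
    sd = logm.std(axis=1, keepdims=True)
    ok = sd.ravel() > 0
    dropped = int((~ok).sum())
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d constant peak rows dropped before z-scoring", dropped
        )
    zmat = (logm[ok] - mu[ok]) / sd[ok]
    peaks = [p for p, good in zip(peak_set, ok) if good]
    if len(peaks) < k:
        raise ValueError("fewer usable peaks than clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(zmat) + 1
    zframe = pd.DataFrame(zmat, index=peaks, columns=pb.columns)
    return pd.Series(labels, index=peaks, name="module"), zframe


def hypergeom_motif_enrichment(
    cluster_peaks: list[str],
    motifs: MotifMatchMatrix,
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric motif enrichment of a peak cluster.

    Universe N = all tested peaks, K = motif-matched peaks in the universe,
    n = cluster size, k = overlap; p = P[X >= k] for X ~ Hypergeom(N, K, n);
    fold = (k/n) / (K/N). Motifs with K = 0 are skipped. BH-FDR across
    tested motifs.
    """
    uni_index = {p: i for i, p in enumerate(universe)}
    missing = [p for p in cluster_peaks if p not in uni_index]
    if missing:
        raise ValueError(f"cluster peaks outside the universe: {missing[:5]}")
    N = len(universe)
    n = len(cluster_peaks)
    cluster_rows = np.array([uni_index[p] for p in cluster_peaks], dtype=np.int64)

    M = motifs.matches
    if M.shape[0] != N:
        raise ValueError("motif matrix rows must align with the peak universe")
    rows = []
    for j, motif in enumerate(motifs.motif_ids):
        col = np.asarray(M[:, j].todense()).ravel().astype(bool)
        K = int(col.sum())
        if K == 0:
            continue
        k = int(col[cluster_rows].sum())
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((motif, k, K, p, fold))
    out = pd.DataFrame(
        rows, columns=["motif", "overlap", "motif_peaks", "pvalue", "fold"]
    ).set_index("motif")
    if len(out):
        out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out.sort_values("pvalue", kind="mergesort")
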