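"""Perturbed co-varying TF-TF accessibility networks.

A perturbation rewires which motif accessibilities co-vary across cells.
For a target, the motif-by-motif correlation over its cells minus the same
correlation over non-targeting cells (Δr) highlights gained and lost
co-regulation; hierarchical clustering of Δr rows splits the motifs into
modules (complete linkage, Euclidean, cut at k — mirroring hclust/cutree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata


def tf_tf_correlation(
    dev: pd.DataFrame, cells: list[str], method: str = "pearson"
) -> pd.DataFrame:
    """Motif x motif correlation of deviation scores over the given cells.

    Zero-variance (or NaN) motifs give NaN rows/columns; the diagonal of
    defined motifs is exactly 1.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells for correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    mat = dev.loc[cells].to_numpy(dtype=float)
    if method == "spearman":
        mat = np.apply_along_axis(rankdata, 0, mat)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    ok = np.isfinite(sd) & (sd > 0) & np.all(np.isfinite(mat), axis=0)
    centered = mat - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centered.T @ centered / mat.shape[0]
        corr = cov / np.outer(sd, sd)
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    np.fill_diagonal(corr, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(corr, index=dev.columns, columns=dev.columns)


def diff_correlation(
    dev: pd.DataFrame,
    target_cells: list[str],
    nt_cells: list[str],
    method: str = "pearson",
) -> pd.DataFrame:
    """Δr = correlation(target cells) − correlation(non-targeting cells).

    Symmetric with zero diagonal; entries lie in [−2, 2]. NaN columns from
    either side propagate.
    """
    r_t = tf_tf_correlation(dev, target_cells, method=method)
    r_nt = tf_tf_correlation(dev, nt_cells, method=method)
    return r_t - r_nt


@dataclass
class ModuleAssignment:
    """Motif -> module labels from hierarchical clustering of Δr rows."""

    modules: pd.Series  # int labels 1..k
    excluded: list[str]  # motifs with undefined Δr rows
    linkage_method: str = "complete"
    metric: str = "euclidean"


def cluster_modules(delta: pd.DataFrame, k: int = 5) -> ModuleAssignment:
    """Agglomerative modules of the differential-correlation matrix.

    Rows with any undefined entry are excluded (and reported); the rest are
    clustered with complete linkage on Euclidean row distances and the
    dendrogram is cut at ``k`` clusters. Deterministic.
    """
    diag = np.diag(delta.to_numpy())
    defined = [m for m, d in zip(delta.index, diag) if np.isfinite(d)]
    excluded = [m for m in delta.index if m not in set(defined)]
    if len(defined) < k:
        raise ValueError("fewer defined motifs than requested modules")
    sub = delta.loc[defined, defined].to_numpy()
    Z = linkage(pdist(sub, metric="euclidean"), method="complete")
    labels = cut_tree(Z, n_clusters=k).ravel() + 1
    return ModuleAssignment(
        modules=pd.Series(labels, index=defined, name="module"),
        excluded=excluded,
    )
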