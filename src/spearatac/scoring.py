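"""Perturbation scoring against non-targeting controls.

The sgRNA:TF score of a perturbation for a motif is the mean motif
deviation of its cells minus the non-targeting mean (ΔD); hits are ranked
by |ΔD|. Redundant motifs are collapsed to one representative per family
(highest deviation variability). A depth-matched Wilcoxon rank-sum test on
deviation z-scores provides per-motif significance for the large screens,
and per-screen maxima are averaged to rank motifs across screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests


def sgrna_tf_scores(group_means: pd.DataFrame, nt_group: str) -> pd.DataFrame:
    """ΔD table: per (group, motif), mean deviation minus the NT mean.

    ``group_means`` is groups x motifs (from ``target_mean_deviations``).
    Returns a long-form DataFrame with columns group, motif, delta_dev,
    abs_delta, rank (1 = largest |ΔD| over all group/motif pairs).
    """
    if nt_group not in group_means.index:
        raise ValueError(f"non-targeting group {nt_group!r} not present")
    delta = group_means.sub(group_means.loc[nt_group], axis=1)
    long = delta.stack(future_stack=True).rename("delta_dev").reset_index()
    long.columns = ["group", "motif", "delta_dev"]
    long["abs_delta"] = long["delta_dev"].abs()
    long = long.sort_values(
        ["abs_delta", "group", "motif"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    long["rank"] = np.arange(1, len(long) + 1)
    return long


def top_hits(scores: pd.DataFrame, exclude_groups: tuple[str, ...] = ()) -> pd.DataFrame:
    """Best motif per group by |ΔD| (the per-target hit report)."""
    sub = scores[~scores["group"].isin(exclude_groups)]
    idx = sub.groupby("group")["abs_delta"].idxmax()
    return sub.loc[idx].set_index("group").sort_values("abs_delta", ascending=False)


@dataclass
class MotifClusterMap:
    """Family de-duplication: retained motif per cluster plus variability."""

    retained: list[str]
    cluster_of: dict[str, str]
    variability: pd.Series


def dedup_motifs(
    variability: pd.Series, clusters: dict[str, str]
) -> MotifClusterMap:
    """Keep the highest-variability motif of each family/cluster.

    Ties break to the lexicographically first motif id. Motifs with NaN
    variability lose to any finite competitor.
    """
    missing = [m for m in variability.index if m not in clusters]
    if missing:
        raise ValueError(f"motifs without a cluster: {missing[:5]}")
    frame = pd.DataFrame(
        {
            "var": variability,
            "cluster": [clusters[m] for m in variability.index],
        }
    )
    frame["var_filled"] = frame["var"].fillna(-np.inf)
    frame = frame.sort_index(kind="mergesort").sort_values(
        "var_filled", ascending=False, kind="mergesort"
    )
    retained = frame.groupby("cluster", sort=False).head(1).index.tolist()
    return MotifClusterMap(
        retained=sorted(retained), cluster_of=dict(clusters), variability=variability
    )


def cross_screen_rank(score_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Rank motifs by the mean over screens of the per-screen max |ΔD|.

    Each table is an ``sgrna_tf_scores`` output for one screen. Motifs not
    present in every screen are excluded (with a recorded count). Returns
    motifs sorted by descending final score.
    """
    if not score_tables:
        raise ValueError("need at least one screen")
    maxima = []
    for tab in score_tables:
        maxima.append(tab.groupby("motif")["abs_delta"].max())
    common = maxima[0].index
    for m in maxima[1:]:
        common = common.intersection(m.index)
    dropped = sorted(set().union(*(m.index for m in maxima)) - set(common))
    mat = pd.DataFrame({i: m.loc[common] for i, m in enumerate(maxima)})
    out = pd.DataFrame(
        {"score": mat.mean(axis=1), "n_screens": mat.shape[1]}
    ).sort_values("score", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["excluded_motifs"] = dropped
    return out


def _depth_match(
    target_depths: np.ndarray,
    nt_depths: np.ndarray,
    buffer_ratio: float,
) -> np.ndarray:
    """Greedy pairing of NT cells to target cells by fragment-depth ratio.

    An NT cell matches a target cell when their depth ratio lies within
    [buffer_ratio, 1/buffer_ratio]. Each NT cell is used at most once.
    Returns indices into ``nt_depths`` of the matched background.
    """
    lo, hi = buffer_ratio, 1.0 / buffer_ratio
    order_nt = np.argsort(nt_depths)
    sorted_nt = nt_depths[order_nt]
    used = np.zeros(len(nt_depths), dtype=bool)
    picked = []
    for d in np.sort(target_depths):
        j0 = np.searchsorted(sorted_nt, d * lo, side="left")
        j1 = np.searchsorted(sorted_nt, d * hi, side="right")
        for j in range(j0, j1):
            if not used[j]:
                used[j] = True
                picked.append(order_nt[j])
                break
    return np.asarray(picked, dtype=np.int64)


def wilcoxon_diff_motifs(
    z: pd.DataFrame,
    target_cells: list[str],
    nt_cells: list[str],
    depths: pd.Series | None = None,
    max_cells: int = 250,
    buffer_ratio: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-motif two-sided rank-sum test of target vs background z-scores.

    Each side is subsampled to ``max_cells`` (seeded); when ``depths`` is
    given, the background is restricted to NT cells depth-matched to the
    target cells within a [buffer_ratio, 1/buffer_ratio] ratio window
    (greedy pairing), falling back to all NT cells if none match. Uses the
    tie-corrected normal approximation; BH-FDR across motifs.
    """
    if len(target_cells) < 2 or len(nt_cells) < 2:
        raise ValueError("need at least 2 cells per side")
    rng = np.random.default_rng(seed)
    tcells = list(target_cells)
    if len(tcells) > max_cells:
        tcells = list(np.array(tcells)[rng.choice(len(tcells), max_cells, replace=False)])

    bcells = list(nt_cells)
    if depths is not None:
        t_d = depths.loc[tcells].to_numpy(dtype=float)
        nt_d = depths.loc[bcells].to_numpy(dtype=float)
        picked = _depth_match(t_d, nt_d, buffer_ratio)
        if len(picked) >= 2:
            bcells = [bcells[j] for j in picked]
    if len(bcells) > max_cells:
        bcells = list(np.array(bcells)[rng.choice(len(bcells), max_cells, replace=False)])

    tz = z.loc[tcells].to_numpy(dtype=float)
    bz = z.loc[bcells].to_numpy(dtype=float)
    motifs = z.columns
    stats = np.full(len(motifs), np.nan)
    pvals = np.ones(len(motifs))
    deltas = np.full(len(motifs), np.nan)
    for j in range(len(motifs)):
        x = tz[:, j]
        y = bz[:, j]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            continue
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stats[j] = len(x) * len(y) / 2.0
            pvals[j] = 1.0
            deltas[j] = 0.0
            continue
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stats[j] = res.statistic
        pvals[j] = res.pvalue
        deltas[j] = np.mean(x) - np.mean(y)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "statistic": stats,
            "mean_diff": deltas,
            "pvalue": pvals,
            "fdr": fdr,
            "n_target": len(tcells),
            "n_background": len(bcells),
        },
        index=pd.Index(motifs, name="motif"),
    )
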