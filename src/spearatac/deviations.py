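"""Bias-corrected motif accessibility deviations per cell.

For a motif's peak set S, the observed accessibility of cell i is the sum
of its counts over S; the expected value assumes the cell distributes its
total counts across peaks proportionally to population-wide peak totals.
The raw deviation Y = (observed - expected) / expected is corrected by
subtracting the mean of the same statistic over bias-matched background
peak sets (matched on GC content and mean accessibility), and the z-score
divides by the background standard deviation. Motif variability is the
standard deviation of z across cells — used downstream to pick one
representative motif per redundant family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from spearatac.containers import MotifMatchMatrix, SparseCountMatrix


@dataclass
class BiasCovariates:
    """Per-peak GC fraction and log1p mean accessibility."""

    gc: np.ndarray
    log1p_mean: np.ndarray

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        self.log1p_mean = np.asarray(self.log1p_mean, dtype=float)
        if self.gc.shape != self.log1p_mean.shape:
            raise ValueError("covariate arrays must align")
        if np.any((self.gc < 0) | (self.gc > 1)) or not np.all(np.isfinite(self.gc)):
            raise ValueError("gc fractions must be finite and in [0, 1]")

    @property
    def n_peaks(self) -> int:
        return len(self.gc)


def compute_bias(counts: SparseCountMatrix, gc: pd.Series | np.ndarray) -> BiasCovariates:
    """Assemble the background-matching covariates for every peak."""
    if isinstance(gc, pd.Series):
        missing = [p for p in counts.col_ids if p not in gc.index]
        if missing:
            raise ValueError(f"peaks missing GC values: {missing[:5]}")
        gc = gc.loc[counts.col_ids].to_numpy()
    gc = np.asarray(gc, dtype=float)
    if len(gc) != counts.shape[1]:
        raise ValueError("gc must cover every peak")
    mean_acc = counts.col_totals().astype(float) / counts.shape[0]
    return BiasCovariates(gc=gc, log1p_mean=np.log1p(mean_acc))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def sample_background_peaks(
    bias: BiasCovariates,
    n_iterations: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Draw bias-matched background peaks for each peak.

    Both covariates are standardized and gridded into ``n_bins`` x
    ``n_bins`` cells; each peak's backgrounds are uniform draws (with
    replacement) from its own bin. A zero-variance covariate collapses
    that axis to a single bin. Returns an (n_peaks, n_iterations) index
    array, deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    gc_z = _standardize(bias.gc)
    acc_z = _standardize(bias.log1p_mean)

    def _bin(x: np.ndarray) -> np.ndarray:
        if np.all(x == 0):
            return np.zeros(len(x), dtype=np.int64)
        edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
        return np.searchsorted(edges, x, side="right")

    bin_id = _bin(gc_z) * n_bins + _bin(acc_z)
    out = np.empty((bias.n_peaks, n_iterations), dtype=np.int64)
    for b in np.unique(bin_id):
        members = np.where(bin_id == b)[0]
        draws = rng.integers(0, len(members), size=(len(members), n_iterations))
        out[members] = members[draws]
    return out


@dataclass
class DeviationResult:
    """Cells x motifs corrected deviations and z-scores."""

    deviations: np.ndarray  # corrected deviation, NaN where undefined
    z: np.ndarray
    raw: np.ndarray  # uncorrected deviation Y = (o - e) / e
    cell_ids: list[str]
    motif_ids: list[str]
    variability: np.ndarray  # per-motif std of z across cells (NaN-aware)
    undefined_motifs: list[str]  # motifs with no matching peak or zero expectation

    def deviations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.deviations, index=self.cell_ids, columns=self.motif_ids)

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.cell_ids, columns=self.motif_ids)


def compute_deviations(
    counts: SparseCountMatrix,
    motifs: MotifMatchMatrix,
    backgrounds: np.ndarray,
) -> DeviationResult:
    """Corrected motif deviations and z-scores for every cell.

    With f_p the population fraction of counts in peak p and T_i the total
    of cell i, expectation e = T_i * sum_{p in S} f_p, raw deviation
    Y = (o - e) / e, corrected deviation Y - mean_b(Y_b) over background
    iterations, z = corrected / sd_b(Y_b). Undefined entries (no matching
    peaks, zero expectation, or zero background spread) are NaN.
    """
    X = counts.matrix.astype(float)
    n_cells, n_peaks = X.shape
    if motifs.n_peaks != n_peaks:
        raise ValueError("motif matrix peak dimension does not match counts")
    if backgrounds.shape[0] != n_peaks:
        raise ValueError("background sets do not cover every peak")
    if backgrounds.max() >= n_peaks or backgrounds.min() < 0:
        raise ValueError("background index out of range")
    T = np.asarray(X.sum(axis=1)).ravel()
    if np.any(T <= 0):
        raise ValueError("every cell must have a positive count total")
    grand = T.sum()
    f = np.asarray(X.sum(axis=0)).ravel() / grand

    M = motifs.matches.astype(float)
    n_motifs = motifs.n_motifs
    peaks_per_motif = np.asarray(M.sum(axis=0)).ravel()

    def _raw(perm: np.ndarray | None) -> np.ndarray:
        """Raw deviation with peaks remapped through ``perm`` (None = identity)."""
        if perm is None:
            Mp = M
        else:
            S = sp.coo_matrix(
                (np.ones(n_peaks), (perm, np.arange(n_peaks))),
                shape=(n_peaks, n_peaks),
            ).tocsr()
            Mp = S @ M
        fsum = np.asarray(Mp.T @ f).ravel()
        o = np.asarray((X @ Mp).todense())
        e = np.outer(T, fsum)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(e > 0, (o - e) / e, np.nan)

    Y = _raw(None)
    n_iter = backgrounds.shape[1]
    # two-pass mean/sd over background iterations avoids cancellation
    Yb_stack = np.stack([_raw(backgrounds[:, b]) for b in range(n_iter)])
    bg_mean = Yb_stack.mean(axis=0)
    bg_sd = Yb_stack.std(axis=0, ddof=1)

    corrected = Y - bg_mean
    # sd below numerical noise means the backgrounds were effectively
    # identical: z is undefined there, not huge
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bg_sd > 1e-12, corrected / bg_sd, np.nan)

    no_peaks = peaks_per_motif == 0
    corrected[:, no_peaks] = np.nan
    z[:, no_peaks] = np.nan
    Y = Y.copy()
    Y[:, no_peaks] = np.nan
    undefined = [
        m
        for j, m in enumerate(motifs.motif_ids)
        if no_peaks[j] or np.all(~np.isfinite(corrected[:, j]))
    ]
    with np.errstate(invalid="ignore"):
        variability = np.array(
            [
                np.nanstd(z[:, j]) if np.any(np.isfinite(z[:, j])) else np.nan
                for j in range(n_motifs)
            ]
        )
    return DeviationResult(
        deviations=corrected,
        z=z,
        raw=Y,
        cell_ids=list(counts.row_ids),
        motif_ids=list(motifs.motif_ids),
        variability=variability,
        undefined_motifs=undefined,
    )


def target_mean_deviations(
    dev: DeviationResult,
    assignments: pd.DataFrame,
    level: str = "target",
    use: str = "deviations",
) -> pd.DataFrame:
    """Mean motif deviation per sgRNA or per target group.

    ``level`` is "target" or "sgrna"; ``use`` selects corrected deviations
    or z-scores. NaN-flagged motif entries propagate (the group mean of an
    all-NaN column is NaN). Groups with zero assigned cells are dropped.
    """
    if level not in ("target", "sgrna"):
        raise ValueError("level must be 'target' or 'sgrna'")
    if use not in ("deviations", "z"):
        raise ValueError("use must be 'deviations' or 'z'")
    mat = dev.deviations if use == "deviations" else dev.z
    frame = pd.DataFrame(mat, index=dev.cell_ids, columns=dev.motif_ids)
    assigned = assignments[assignments["assigned"]]
    missing = [c for c in assigned.index if c not in frame.index]
    if missing:
        raise ValueError(f"assigned cells missing from deviations: {missing[:5]}")
    labels = assigned[level]
    sub = frame.loc[assigned.index]
    return sub.groupby(labels).mean()
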