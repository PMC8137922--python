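"""Ground-truthed synthetic screens.

Emulates the two raw inputs of a pooled CRISPRi screen with an
accessibility read-out: (1) targeted sgRNA-enrichment fastq pairs (spacer
read + cell-barcode index read) with barcode-swapping contamination and
sequencing errors, and (2) per-cell peak insertion counts with
depth-varying Poisson (optionally Gamma-Poisson) noise and injected
motif-level fold-changes for each target. GC content is drawn
independently of the effects by default so that bias-matched background
sampling cannot absorb true signal; a confounded mode exists to
demonstrate why the matching matters. Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from spearatac.containers import FragmentRecord, IntervalSet, MotifMatchMatrix, SparseCountMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic screen.

    Defaults emulate a 12-target screen with 3 sgRNAs per target and 3
    non-targeting sgRNAs at roughly 200 cells per target arm, each target
    doubling the accessibility of one motif's peaks.
    """

    n_targets: int = 12
    sgrnas_per_target: int = 3
    n_nt_sgrnas: int = 3
    cells_per_sgrna: int = 67
    reads_per_cell_mu: float = float(np.log(100.0))  # log-normal, median 100 reads
    reads_per_cell_sigma: float = 0.3
    barcode_length: int = 16
    spacer_length: int = 20
    contamination: float = 0.05  # fraction of a cell's reads from other sgRNAs
    seq_error_rate: float = 0.001  # per-base substitution rate
    n_peaks: int = 1500
    n_motifs: int = 20  # first n_targets motifs carry the injected effects
    peaks_per_motif: int = 50
    baseline_shape: float = 2.0  # Gamma shape for per-peak baseline rates
    mean_insertions_per_cell: float = 4000.0
    depth_sigma: float = 0.5  # log-normal spread of per-cell depth factors
    effect_fold: float = 2.0  # fold-change on each target's motif peaks
    effects: dict[str, tuple[str, float]] | None = None  # override target->(motif, fold)
    doublet_rate: float = 0.0
    overdispersion: float | None = None  # Gamma-Poisson shape; None = pure Poisson
    gc_confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.contamination < 0.5):
            raise ValueError("contamination must be in [0, 0.5): assignment guarantee void")
        for rate in (self.seq_error_rate, self.doublet_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.effect_fold <= 0:
            raise ValueError("fold-changes must be positive")
        if self.n_motifs < self.n_targets:
            raise ValueError("need at least one motif per target")
        if self.n_peaks < self.n_motifs * self.peaks_per_motif:
            raise ValueError("n_peaks too small for disjoint motif peak sets")

    # --- derived layout -------------------------------------------------
    def target_names(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_targets)]

    def motif_names(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_motifs)]

    def sgrna_table(self) -> pd.DataFrame:
        rows = []
        for t in self.target_names():
            for j in range(self.sgrnas_per_target):
                rows.append((f"sg{t}-{j + 1}", t))
        for j in range(self.n_nt_sgrnas):
            rows.append((f"sgNT-{j + 1}", "NT"))
        return pd.DataFrame(rows, columns=["sgrna_id", "target"])

    def effect_map(self) -> dict[str, tuple[str, float]]:
        if self.effects is not None:
            return dict(self.effects)
        motifs = self.motif_names()
        return {
            t: (motifs[i], self.effect_fold)
            for i, t in enumerate(self.target_names())
        }


@dataclass
class GroundTruth:
    """True per-cell labels and injected structure of a simulated screen."""

    cells: pd.DataFrame  # index cell barcode; columns sgrna, target, doublet
    spacer_library: pd.DataFrame  # spacer, sgrna_id, target
    whitelist: list[str]
    effects: dict[str, tuple[str, float]]
    motif_peaks: dict[str, list[int]] = field(default_factory=dict)


def _random_distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random DNA sequences, unique and pairwise Hamming distance >= 2."""
    seqs: list[str] = []
    variants: set[str] = set()
    while len(seqs) < n:
        s = "".join(rng.choice(_BASES, size=length))
        if s in variants:
            continue
        svars = {s}
        for i in range(length):
            for b in "ACGT":
                if b != s[i]:
                    svars.add(s[:i] + b + s[i + 1 :])
        if svars & variants:
            continue
        variants |= svars
        seqs.append(s)
    return seqs


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.where(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return "".join(arr)


def build_truth(config: SimulationConfig) -> GroundTruth:
    """Assign barcodes, spacers, and true labels for every simulated cell."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lib = config.sgrna_table()
    n_sgrnas = len(lib)
    n_cells = n_sgrnas * config.cells_per_sgrna
    barcodes = _random_distinct_seqs(rng, n_cells, config.barcode_length)
    spacers = _random_distinct_seqs(rng, n_sgrnas, config.spacer_length)
    lib = lib.assign(spacer=spacers)[["spacer", "sgrna_id", "target"]]

    cell_sgrnas = np.repeat(lib["sgrna_id"].to_numpy(), config.cells_per_sgrna)
    targets = np.repeat(lib["target"].to_numpy(), config.cells_per_sgrna)
    doublet = np.zeros(n_cells, dtype=bool)
    if config.doublet_rate > 0:
        n_doub = int(round(config.doublet_rate * n_cells))
        doublet[rng.choice(n_cells, size=n_doub, replace=False)] = True
    cells = pd.DataFrame(
        {"sgrna": cell_sgrnas, "target": targets, "doublet": doublet},
        index=pd.Index(barcodes, name="cell"),
    )
    return GroundTruth(
        cells=cells,
        spacer_library=lib,
        whitelist=barcodes,
        effects=config.effect_map(),
    )


def simulate_sgrna_fastq(
    config: SimulationConfig,
    spacer_path: str | Path,
    index_path: str | Path,
    truth: GroundTruth | None = None,
) -> GroundTruth:
    """Write the spacer/index FASTQ pair for a simulated enrichment library.

    Each cell draws a log-normal number of reads; each read carries the
    cell's true spacer with probability 1 - contamination and a uniformly
    random other spacer otherwise, then per-base substitution errors are
    applied to both mates. Byte-identical output for a given seed.
    """
    if truth is None:
        truth = build_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lib = truth.spacer_library
    spacer_of = dict(zip(lib["sgrna_id"], lib["spacer"]))
    all_spacers = lib["spacer"].tolist()
    qual_sp = "I" * config.spacer_length
    qual_bc = "I" * config.barcode_length

    with open(spacer_path, "wt") as f_sp, open(index_path, "wt") as f_bc:
        read_no = 0
        for barcode, row in truth.cells.iterrows():
            true_spacer = spacer_of[row["sgrna"]]
            n_reads = max(1, int(round(rng.lognormal(
                config.reads_per_cell_mu, config.reads_per_cell_sigma
            ))))
            for _ in range(n_reads):
                read_no += 1
                if config.contamination > 0 and rng.random() < config.contamination:
                    spacer = all_spacers[rng.integers(len(all_spacers))]
                else:
                    spacer = true_spacer
                sp_read = _mutate(rng, spacer, config.seq_error_rate)
                bc_read = _mutate(rng, barcode, config.seq_error_rate)
                f_sp.write(f"@read{read_no}\n{sp_read}\n+\n{qual_sp}\n")
                f_bc.write(f"@read{read_no}\n{bc_read}\n+\n{qual_bc}\n")
    return truth


def simulate_counts(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[SparseCountMatrix, MotifMatchMatrix, pd.Series, GroundTruth]:
    """Simulate the cells x peaks insertion-count matrix with injected effects.

    X_ip ~ Poisson(d_i * lambda_p * e_ip): d_i a log-normal per-cell depth
    factor (mean 1), lambda_p a Gamma baseline scaled so the expected cell
    total is ``mean_insertions_per_cell``, and e_ip the target's fold-change
    on peaks of its perturbed motif (1 elsewhere). Motif peak sets are
    disjoint blocks. Doublet cells add an independent second draw from a
    random other cell's rate vector. Returns (counts, motif matches,
    per-peak GC fractions, truth).
    """
    if truth is None:
        truth = build_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_cells = len(truth.cells)
    n_peaks = config.n_peaks

    lam = rng.gamma(config.baseline_shape, 1.0, size=n_peaks)
    lam *= config.mean_insertions_per_cell / lam.sum()
    depth = rng.lognormal(-config.depth_sigma**2 / 2, config.depth_sigma, size=n_cells)

    motif_names = config.motif_names()
    peak_order = rng.permutation(n_peaks)
    motif_peaks: dict[str, list[int]] = {}
    pos = 0
    for m in motif_names:
        motif_peaks[m] = sorted(peak_order[pos : pos + config.peaks_per_motif].tolist())
        pos += config.peaks_per_motif
    truth.motif_peaks = motif_peaks

    effects = truth.effects
    fold = np.ones((n_cells, 1))
    e_by_target: dict[str, np.ndarray] = {}
    for t, (motif, f) in effects.items():
        vec = np.ones(n_peaks)
        vec[motif_peaks[motif]] = f
        e_by_target[t] = vec
    ones = np.ones(n_peaks)

    rates = np.empty((n_cells, n_peaks))
    tlabels = truth.cells["target"].to_numpy()
    for i in range(n_cells):
        rates[i] = depth[i] * lam * e_by_target.get(tlabels[i], ones)

    if config.overdispersion is not None:
        a = config.overdispersion
        rates = rates * rng.gamma(a, 1.0 / a, size=rates.shape)
    X = rng.poisson(rates)

    doublet_idx = np.where(truth.cells["doublet"].to_numpy())[0]
    for i in doublet_idx:
        j = int(rng.integers(n_cells))
        X[i] += rng.poisson(rates[j])

    if config.gc_confounded:
        gc = np.full(n_peaks, 0.5)
        perturbed = np.concatenate(
            [motif_peaks[m] for m, _ in effects.values()]
        ) if effects else np.array([], dtype=int)
        gc += rng.uniform(-0.05, 0.05, size=n_peaks)
        gc[np.unique(perturbed)] += 0.15
        gc = np.clip(gc, 0.0, 1.0)
    else:
        gc = rng.uniform(0.3, 0.7, size=n_peaks)

    peak_ids = [f"peak{p + 1}" for p in range(n_peaks)]
    counts = SparseCountMatrix(
        sp.csr_matrix(X), truth.cells.index.tolist(), peak_ids
    )
    rows, cols = [], []
    for j, m in enumerate(motif_names):
        rows.extend(motif_peaks[m])
        cols.extend([j] * len(motif_peaks[m]))
    matches = sp.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)),
        shape=(n_peaks, len(motif_names)),
    ).tocsc()
    clusters = {m: f"fam_{m}" for m in motif_names}
    motifs = MotifMatchMatrix(matches, motif_names, clusters)
    gc_series = pd.Series(gc, index=peak_ids, name="gc")
    return counts, motifs, gc_series, truth


def simulate_fragments(
    config: SimulationConfig,
    counts: SparseCountMatrix,
    peak_spacing: int = 4500,
    peak_width: int = 500,
) -> tuple[list[FragmentRecord], IntervalSet, IntervalSet, dict[str, int]]:
    """Lay the simulated peaks on a synthetic chromosome and emit fragments.

    Peaks are evenly spaced on "chr1"; each cell's insertion count at a
    peak is realized as fragments whose insertions fall inside the peak
    (one insertion spills into the adjacent gap when the count is odd).
    TSS sites are placed at peak midpoints, so flank windows fall in the
    sparse inter-peak gaps and real cells show high TSS enrichment.
    Returns (fragments, peaks, tss sites, chrom sizes).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n_peaks = len(counts.col_ids)
    starts = np.arange(n_peaks) * peak_spacing + 1000
    ends = starts + peak_width
    chrom_size = int(ends[-1] + peak_spacing)
    peaks = IntervalSet(
        pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": ends, "name": counts.col_ids}
        )
    )
    tss = IntervalSet(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "start": (starts + peak_width // 2),
                "end": (starts + peak_width // 2 + 1),
            }
        )
    )
    frags: list[FragmentRecord] = []
    coo = counts.matrix.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        barcode = counts.row_ids[i]
        s, e = starts[j], ends[j]
        n_pairs, odd = divmod(int(v), 2)
        for _ in range(n_pairs):
            a, b = sorted(rng.integers(s, e, size=2))
            frags.append(FragmentRecord("chr1", int(a), int(b) + 1, barcode, 1))
        if odd:
            a = int(rng.integers(s, e))
            gap_pos = int(rng.integers(e + 600, e + 1200))
            frags.append(FragmentRecord("chr1", a, gap_pos + 1, barcode, 1))
    frags.sort(key=lambda f: (f.chrom, f.start, f.end, f.barcode))
    return frags, peaks, tss, {"chr1": chrom_size}
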