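import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spearatac.containers import MotifMatchMatrix
from spearatac.deviations import (
    BiasCovariates,
    compute_bias,
    compute_deviations,
    sample_background_peaks,
    target_mean_deviations,
)
from spearatac.synthetic import SimulationConfig, build_truth, simulate_counts

from conftest import counts_from_dense, truth_assignments


def motif_matrix(n_peaks, peak_sets):
    """Build a MotifMatchMatrix from {motif: [peak indices]}."""
    cols = list(peak_sets)
    mat = np.zeros((n_peaks, len(cols)), dtype=bool)
    for j, m in enumerate(cols):
        mat[peak_sets[m], j] = True
    return MotifMatchMatrix(sp.csc_matrix(mat), cols, {m: m for m in cols})


def brute_force_deviations(X, M, B):
    """Independent loop-based oracle for the deviation statistics."""
    X = np.asarray(X, dtype=float)
    n_cells, n_peaks = X.shape
    n_motifs = M.shape[1]
    n_iter = B.shape[1]
    T = X.sum(axis=1)
    f = X.sum(axis=0) / X.sum()
    raw = np.full((n_cells, n_motifs), np.nan)
    corrected = np.full((n_cells, n_motifs), np.nan)
    z = np.full((n_cells, n_motifs), np.nan)
    for m in range(n_motifs):
        S = np.where(M[:, m])[0]
        if len(S) == 0:
            continue
        Yb = np.full((n_iter, n_cells), np.nan)
        for i in range(n_cells):
            e = T[i] * f[S].sum()
            if e > 0:
                raw[i, m] = (X[i, S].sum() - e) / e
        for b in range(n_iter):
            Sb = B[S, b]
            for i in range(n_cells):
                e = T[i] * f[Sb].sum()
                if e > 0:
                    Yb[b, i] = (X[i, Sb].sum() - e) / e
        mean_b = Yb.mean(axis=0)
        sd_b = Yb.std(axis=0, ddof=1)
        for i in range(n_cells):
            corrected[i, m] = raw[i, m] - mean_b[i]
            # sd at floating-point noise level means the backgrounds were
            # effectively identical: z undefined (same rule as the library)
            if sd_b[i] > 1e-12:
                z[i, m] = corrected[i, m] / sd_b[i]
    return raw, corrected, z


class TestBias:
    def test_log1p_mean_accessibility(self):
        counts = counts_from_dense(np.vstack([np.zeros(2)] * 9 + [[0, 10]]))
        bias = compute_bias(counts, np.array([0.4, 0.6]))
        assert bias.log1p_mean == pytest.approx([0.0, np.log1p(1.0)])

    def test_identical_peaks_identical_covariates(self):
        counts = counts_from_dense([[2, 2], [3, 3]])
        bias = compute_bias(counts, np.array([0.5, 0.5]))
        assert bias.gc[0] == bias.gc[1] and bias.log1p_mean[0] == bias.log1p_mean[1]

    def test_gc_out_of_range_rejected(self):
        counts = counts_from_dense([[1, 1]])
        with pytest.raises(ValueError):
            compute_bias(counts, np.array([0.5, 1.5]))

    def test_missing_gc_rejected(self):
        counts = counts_from_dense([[1, 1]])
        with pytest.raises(ValueError):
            compute_bias(counts, pd.Series({"p0": 0.5}))


class TestBackgroundSampling:
    def test_identical_covariates_sample_all_peaks(self):
        bias = BiasCovariates(gc=np.full(40, 0.5), log1p_mean=np.full(40, 1.0))
        bg = sample_background_peaks(bias, n_iterations=200, seed=1)
        assert set(np.unique(bg)) == set(range(40))

    def test_separated_clusters_stay_within_cluster(self):
        gc = np.array([0.2] * 10 + [0.8] * 10)
        acc = np.array([0.5] * 10 + [3.0] * 10)
        bg = sample_background_peaks(BiasCovariates(gc, acc), n_iterations=50, seed=2)
        assert bg[:10].max() < 10 and bg[10:].min() >= 10

    def test_deterministic_given_seed(self):
        bias = BiasCovariates(gc=np.linspace(0.3, 0.7, 30), log1p_mean=np.linspace(0, 2, 30))
        a = sample_background_peaks(bias, seed=9)
        b = sample_background_peaks(bias, seed=9)
        assert np.array_equal(a, b)
        c = sample_background_peaks(bias, seed=10)
        assert not np.array_equal(a, c)


class TestComputeDeviations:
    def test_two_cell_example(self):
        counts = counts_from_dense([[2, 0], [0, 2]])
        M = motif_matrix(2, {"m": [0]})
        B = np.zeros((2, 3), dtype=int)  # degenerate backgrounds; raw is the check
        B[:, 0] = [0, 1]
        B[:, 1] = [1, 0]
        B[:, 2] = [0, 1]
        dev = compute_deviations(counts, M, B)
        assert dev.raw[:, 0] == pytest.approx([1.0, -1.0])

    def test_motif_covering_all_peaks_has_zero_raw_deviation(self):
        rng = np.random.default_rng(0)
        counts = counts_from_dense(rng.poisson(2.0, size=(8, 12)) + 1)
        M = motif_matrix(12, {"all": list(range(12))})
        B = sample_background_peaks(
            BiasCovariates(np.full(12, 0.5), np.full(12, 1.0)), n_iterations=10, seed=0
        )
        dev = compute_deviations(counts, M, B)
        assert np.allclose(dev.raw[:, 0], 0.0, atol=1e-12)

    def test_self_background_gives_zero_corrected_and_undefined_z(self):
        counts = counts_from_dense([[2, 1], [1, 3]])
        M = motif_matrix(2, {"m": [0]})
        B = np.tile(np.arange(2)[:, None], (1, 5))  # background == foreground
        dev = compute_deviations(counts, M, B)
        assert np.allclose(dev.deviations[:, 0], 0.0)
        assert np.all(np.isnan(dev.z[:, 0]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cells, n_peaks, n_motifs = 20, 50, 5
        X = rng.poisson(1.5, size=(n_cells, n_peaks))
        X[:, 0] += 1  # keep all cell totals positive
        sets = {
            f"m{j}": rng.choice(n_peaks, size=rng.integers(1, 12), replace=False)
            for j in range(n_motifs - 1)
        }
        sets["empty"] = []
        M = motif_matrix(n_peaks, sets)
        gc = rng.uniform(0.3, 0.7, n_peaks)
        counts = counts_from_dense(X)
        bias = compute_bias(counts, gc)
        B = sample_background_peaks(bias, n_iterations=8, seed=seed)
        dev = compute_deviations(counts, M, B)
        raw, corrected, z = brute_force_deviations(X, M.matches.toarray(), B)
        np.testing.assert_allclose(dev.raw, raw, atol=1e-10)
        np.testing.assert_allclose(dev.deviations, corrected, atol=1e-10)
        np.testing.assert_allclose(dev.z, z, atol=1e-10)
        assert "empty" in dev.undefined_motifs

    def test_invariant_to_duplicating_cells(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, size=(6, 15)) + 1
        M = motif_matrix(15, {"m": [0, 3, 7]})
        B = sample_background_peaks(
            BiasCovariates(rng.uniform(0.3, 0.7, 15), np.zeros(15)), n_iterations=6, seed=1
        )
        d1 = compute_deviations(counts_from_dense(X), M, B)
        dup = counts_from_dense(np.vstack([X, X]))
        d2 = compute_deviations(dup, M, B)
        np.testing.assert_allclose(d2.deviations[:6], d1.deviations, atol=1e-12)

    def test_injected_effect_raises_target_mean_deviation(self):
        """Cells with doubled motif-peak counts score above controls on that
        motif, across independent simulation seeds."""
        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_targets=1, sgrnas_per_target=1, n_nt_sgrnas=1,
                cells_per_sgrna=200, n_peaks=200, n_motifs=4, peaks_per_motif=20,
                mean_insertions_per_cell=400.0, effect_fold=2.0, seed=seed,
            )
            counts, motifs, gc, truth = simulate_counts(cfg)
            bias = compute_bias(counts, gc)
            B = sample_background_peaks(bias, n_iterations=20, seed=seed)
            dev = compute_deviations(counts, motifs, B)
            col = dev.motif_ids.index("M01")
            is_t = (truth.cells["target"] == "T01").to_numpy()
            if dev.deviations[is_t, col].mean() > dev.deviations[~is_t, col].mean():
                wins += 1
        assert wins == 20


class TestTargetMeans:
    def _dev(self, mat, cells, motifs):
        from spearatac.deviations import DeviationResult

        arr = np.asarray(mat, dtype=float)
        return DeviationResult(
            deviations=arr, z=arr.copy(), raw=arr.copy(), cell_ids=cells,
            motif_ids=motifs, variability=np.nanstd(arr, axis=0),
            undefined_motifs=[],
        )

    def test_group_mean(self):
        dev = self._dev([[1.0], [2.0], [5.0]], ["a", "b", "c"], ["m"])
        asg = pd.DataFrame(
            {"sgrna": ["s1", "s1", "s2"], "target": ["T", "T", "NT"],
             "assigned": True, "reason": ""},
            index=["a", "b", "c"],
        )
        means = target_mean_deviations(dev, asg)
        assert means.loc["T", "m"] == 1.5
        assert means.loc["NT", "m"] == 5.0  # singleton group keeps its value

    def test_nan_motif_propagates(self):
        dev = self._dev([[np.nan], [np.nan]], ["a", "b"], ["m"])
        asg = pd.DataFrame(
            {"sgrna": ["s1", "s1"], "target": ["T", "T"], "assigned": True, "reason": ""},
            index=["a", "b"],
        )
        means = target_mean_deviations(dev, asg)
        assert np.isnan(means.loc["T", "m"])
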