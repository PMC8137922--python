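import numpy as np
import pandas as pd
import pytest

from spearatac import io as sio
from spearatac.sgrna import (
    BarcodeIndex,
    SpacerLibrary,
    assign_cells,
    assignment_summary,
    build_count_matrix,
    cost_per_cell,
    match_read,
)
from spearatac.synthetic import SimulationConfig, build_truth, simulate_sgrna_fastq

from conftest import counts_from_dense


def _library(rows):
    return SpacerLibrary(pd.DataFrame(rows, columns=["spacer", "sgrna_id", "target"]))


LIB = _library(
    [
        ("ACGTACGT", "sgA-1", "A"),
        ("TTTTCCCC", "sgA-2", "A"),
        ("GGGGAAAA", "sgNT-1", "NT"),
    ]
)


class TestBarcodeIndex:
    WL = ["AAAA", "CCCC", "GGGG", "AAAT"]

    def test_exact_match_wins(self):
        idx = BarcodeIndex(self.WL)
        # AAAT is itself a whitelist entry even though it is 1 mismatch from AAAA
        assert idx.resolve("AAAT") == "AAAT"

    def test_one_mismatch_resolves_uniquely(self):
        idx = BarcodeIndex(self.WL)
        assert idx.resolve("CCCG") == "CCCC"

    def test_ambiguous_query_returns_none(self):
        idx = BarcodeIndex(self.WL)
        # AAAG is distance 1 from both AAAA and AAAT
        assert idx.resolve("AAAG") is None
        assert idx.is_ambiguous("AAAG")

    def test_matches_brute_force_hamming_scan(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        wl = list({"".join(rng.choice(bases, 6)) for _ in range(60)})
        idx = BarcodeIndex(wl)
        for _ in range(800):
            q = "".join(rng.choice(bases, 6))
            dists = [sum(a != b for a, b in zip(q, w)) for w in wl]
            if q in wl:
                expected = q
            else:
                hits = [w for w, d in zip(wl, dists) if d == 1]
                expected = hits[0] if len(hits) == 1 else None
            assert idx.resolve(q) == expected

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            BarcodeIndex(["AAAA", "CCC"])


class TestMatchRead:
    IDX = BarcodeIndex(["AAAA", "CCCC"])

    def test_both_exact(self):
        assert match_read("ACGTACGTGG", "AAAA", self.IDX, LIB) == ("AAAA", "sgA-1")

    def test_barcode_one_mismatch(self):
        assert match_read("ACGTACGTGG", "AAAC", self.IDX, LIB)[0] == "AAAA"

    def test_unmatched_spacer_returns_none(self):
        assert match_read("NNNNNNNNNN", "AAAA", self.IDX, LIB) == ("AAAA", None)

    def test_scan_window_recovers_offset_spacer(self):
        assert match_read("GACGTACGTG", "AAAA", self.IDX, LIB)[1] is None
        assert match_read("GACGTACGTG", "AAAA", self.IDX, LIB, scan_window=2)[1] == "sgA-1"


class TestCountMatrix:
    IDX = BarcodeIndex(["AAAA", "CCCC"])

    def _stream(self, pairs):
        yield pairs

    def test_repeated_pair_counts(self):
        counts, rep = build_count_matrix(
            self._stream([("ACGTACGT", "AAAA")] * 3), self.IDX, LIB
        )
        assert counts.to_dense()[0].tolist() == [3, 0, 0]
        assert rep.n_both_matched == 3

    def test_distinct_pairs(self):
        pairs = [
            ("ACGTACGT", "AAAA"),
            ("TTTTCCCC", "AAAA"),
            ("ACGTACGT", "CCCC"),
        ]
        counts, _ = build_count_matrix(self._stream(pairs), self.IDX, LIB)
        dense = pd.DataFrame(counts.to_dense(), index=counts.row_ids, columns=counts.col_ids)
        assert dense.loc["AAAA", "sgA-1"] == 1
        assert dense.loc["AAAA", "sgA-2"] == 1
        assert dense.loc["CCCC", "sgA-1"] == 1

    def test_report_bookkeeping_and_conservation(self):
        pairs = [("ACGTACGT", "AAAA")] * 6 + [("ACGTACGT", "TTTT")] * 4
        counts, rep = build_count_matrix(self._stream(pairs), self.IDX, LIB)
        assert rep.n_reads == 10
        assert rep.n_both_matched == 6
        # matrix grand total equals the both-matched read total
        assert counts.matrix.sum() == rep.n_both_matched

    def test_empty_stream(self):
        counts, rep = build_count_matrix(iter([]), self.IDX, LIB)
        assert counts.shape == (0, 3) and rep.n_reads == 0


class TestAssignCells:
    @pytest.mark.parametrize(
        "row, assigned, reason, spec",
        [
            ([18, 2, 0], True, "", 0.90),  # 20 total, specificity 0.9
            ([16, 3, 0], False, "low_counts", 16 / 19),  # 19 < 20
            ([15, 5, 0], False, "low_specificity", 0.75),
            ([10, 10, 0], False, "tie", 0.5),
        ],
    )
    def test_threshold_rule(self, row, assigned, reason, spec):
        counts = counts_from_dense([row])
        counts.col_ids = LIB.sgrna_ids
        table = assign_cells(counts, LIB)
        r = table.iloc[0]
        assert bool(r["assigned"]) is assigned
        assert r["reason"] == reason
        assert r["specificity"] == pytest.approx(spec)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(0)
        counts = counts_from_dense(rng.integers(0, 30, size=(50, 3)))
        counts.col_ids = LIB.sgrna_ids
        prev = None
        for mc, ms in [(5, 0.5), (10, 0.6), (20, 0.8), (30, 0.9)]:
            cur = set(
                assign_cells(counts, LIB, min_counts=mc, min_specificity=ms)
                .query("assigned")
                .index
            )
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_target_level_aggregation_is_looser(self):
        # 12 + 9 reads across two sgRNAs of the same target
        counts = counts_from_dense([[12, 9, 2]])
        counts.col_ids = LIB.sgrna_ids
        per_sg = assign_cells(counts, LIB)
        per_t = assign_cells(counts, LIB, by_target=True)
        assert not per_sg.iloc[0]["assigned"]  # 12/23 < 0.8
        assert per_t.iloc[0]["assigned"]  # 21/23 >= 0.8
        assert per_t.iloc[0]["target"] == "A" and per_t.iloc[0]["sgrna"] == "sgA-1"


class TestSummaryAndCost:
    def _table(self, n_assigned, targets=("A",)):
        rows = []
        for i in range(n_assigned):
            rows.append((f"c{i}", "sg", targets[i % len(targets)], 30, 1.0, True, ""))
        return pd.DataFrame(
            rows,
            columns=["cell", "sgrna", "target", "n_counts", "specificity", "assigned", "reason"],
        ).set_index("cell")

    def test_pilot_screen_rate_rounds_to_48_percent(self):
        s = assignment_summary(self._table(3045), 6390)
        assert s["percent_assigned"] == 48
        assert s["fraction_assigned"] == pytest.approx(3045 / 6390)

    def test_zero_assigned(self):
        s = assignment_summary(self._table(0), 10)
        assert s["fraction_assigned"] == 0

    def test_per_target_counts(self):
        s = assignment_summary(self._table(15, targets=("A", "A", "B")), 20)
        assert s["per_target"] == {"A": 10, "B": 5}
        assert sum(s["per_target"].values()) == s["n_assigned"]

    def test_zero_captured_is_error(self):
        with pytest.raises(ValueError):
            assignment_summary(self._table(0), 0)

    @pytest.mark.parametrize(
        "cost, n, expected", [(1400, 3045, 0.46), (750, 750, 1.00), (100, 3, 33.33)]
    )
    def test_cost_per_cell(self, cost, n, expected):
        assert cost_per_cell(cost, n) == expected

    def test_cost_zero_cells_is_error(self):
        with pytest.raises(ValueError):
            cost_per_cell(100, 0)


class TestEndToEndAssignment:
    def _run(self, tmp_path, **overrides):
        cfg = SimulationConfig(
            n_targets=2,
            sgrnas_per_target=2,
            n_nt_sgrnas=1,
            cells_per_sgrna=12,
            n_peaks=100,
            n_motifs=2,
            peaks_per_motif=10,
            seed=7,
            **overrides,
        )
        truth = build_truth(cfg)
        simulate_sgrna_fastq(cfg, tmp_path / "R1.fq", tmp_path / "I1.fq", truth)
        idx = BarcodeIndex(truth.whitelist)
        lib = SpacerLibrary(truth.spacer_library)
        counts, _ = build_count_matrix(
            sio.read_fastq_pair(tmp_path / "R1.fq", tmp_path / "I1.fq"), idx, lib
        )
        table = assign_cells(counts, lib)
        return table, truth

    def test_no_contamination_gives_perfect_accuracy(self, tmp_path):
        table, truth = self._run(tmp_path, contamination=0.0, seq_error_rate=0.0)
        assigned = table[table["assigned"]]
        assert len(assigned) == len(truth.cells)
        merged = assigned.join(truth.cells, rsuffix="_true")
        assert (merged["sgrna"] == merged["sgrna_true"]).all()

    def test_moderate_contamination_still_recovers_truth(self, tmp_path):
        table, truth = self._run(tmp_path, contamination=0.15)
        assigned = table[table["assigned"]]
        assert (assigned["specificity"] >= 0.8).all()
        merged = assigned.join(truth.cells, rsuffix="_true")
        assert (merged["sgrna"] == merged["sgrna_true"]).all()
        # nearly every cell should still clear the specificity bar
        assert len(assigned) >= 0.9 * len(truth.cells)
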