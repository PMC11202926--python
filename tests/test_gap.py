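import math

import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.gap import (
    GapRow,
    gap_table,
    overlap_report,
    split_lump_report,
    tenfold_criterion,
    threshold_sweep,
)
from barcodekit.simulate import SimulationConfig, simulate


def _two_species_matrix():
    ids = ["a1", "a2", "b1", "b2"]
    d = np.array(
        [
            [0.000, 0.004, 0.080, 0.090],
            [0.004, 0.000, 0.070, 0.085],
            [0.080, 0.070, 0.000, 0.006],
            [0.090, 0.085, 0.006, 0.000],
        ]
    )
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return DistanceMatrix(ids, d), species


class TestGapTable:
    def test_brute_force_two_species(self):
        m, species = _two_species_matrix()
        rows = {r.species: r for r in gap_table(m, species)}
        # min_inter is the smallest cross-species pair, 0.070
        assert rows["A"].min_inter == pytest.approx(7.0)
        assert rows["A"].mean_inter == pytest.approx(100 * (0.08 + 0.09 + 0.07 + 0.085) / 4)
        assert rows["A"].max_intra == pytest.approx(0.4)
        assert rows["B"].nearest_neighbor == "A"

    def test_singleton_species_has_na_intraspecific(self):
        ids = ["a1", "a2", "b1"]
        d = np.array([[0, 0.01, 0.1], [0.01, 0, 0.1], [0.1, 0.1, 0]])
        rows = {r.species: r for r in gap_table(DistanceMatrix(ids, d), {"a1": "A", "a2": "A", "b1": "B"})}
        assert rows["B"].n == 1
        assert rows["B"].max_intra is None and rows["B"].mean_intra is None

    def test_single_species_is_an_error(self):
        ids = ["a1", "a2"]
        d = np.array([[0, 0.01], [0.01, 0]])
        with pytest.raises(ValueError):
            gap_table(DistanceMatrix(ids, d), {"a1": "A", "a2": "A"})


class TestTenfold:
    def test_printed_means_pass(self):
        ratio, passes = tenfold_criterion(8.94, 0.63)
        assert ratio == pytest.approx(14.19, abs=0.005)
        assert passes

    def test_equal_means_fail(self):
        ratio, passes = tenfold_criterion(0.63, 0.63)
        assert ratio == pytest.approx(1.0)
        assert not passes

    def test_zero_intraspecific_passes_with_infinite_ratio(self):
        ratio, passes = tenfold_criterion(5.0, 0.0)
        assert math.isinf(ratio) and passes

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tenfold_criterion(-1.0, 0.5)


class TestOverlapReport:
    @staticmethod
    def _row(sp, n=2, min_inter=10.0, mean_inter=15.0, max_intra=0.5, mean_intra=0.3):
        return GapRow(sp, n, min_inter, mean_inter, max_intra, mean_intra)

    def test_high_intra_reaching_into_low_inter_invalidates_gap(self):
        rows = [
            self._row("X", max_intra=3.29, mean_intra=2.0),
            self._row("Y", min_inter=2.35),
        ]
        verdict = overlap_report(rows)
        assert ("X", "Y") in verdict.overlaps
        assert not verdict.gap_valid

    def test_clean_separation_validates_gap(self):
        rows = [self._row("X"), self._row("Y"), self._row("Z")]
        verdict = overlap_report(rows)
        assert verdict.passes_tenfold and not verdict.overlaps
        assert verdict.gap_valid

    def test_all_singletons_is_indeterminate(self):
        rows = [
            GapRow("X", 1, 10.0, 15.0, None, None),
            GapRow("Y", 1, 12.0, 15.0, None, None),
        ]
        verdict = overlap_report(rows)
        assert verdict.indeterminate and not verdict.gap_valid

    def test_row_permutation_invariance(self):
        rows = [
            self._row("X", max_intra=3.0),
            self._row("Y", min_inter=2.0),
            self._row("Z"),
        ]
        a = overlap_report(rows)
        b = overlap_report(rows[::-1])
        assert a == b


class TestThresholdSweep:
    def test_two_tight_blobs_top_partition_has_two_units(self):
        m, species = _two_species_matrix()
        top = threshold_sweep(m)[0]
        assert top.n_units == 2
        assert split_lump_report(top, species).concordant

    def test_all_identical_sequences_form_one_unit(self):
        ids = ["a", "b", "c"]
        m = DistanceMatrix(ids, np.zeros((3, 3)))
        top = threshold_sweep(m)[0]
        assert top.n_units == 1

    def test_partitions_are_nested_across_thresholds(self, small_matrix):
        parts = sorted(threshold_sweep(small_matrix), key=lambda p: p.threshold)
        for lo, hi in zip(parts[:-1], parts[1:]):
            # units of the higher threshold are unions of lower-threshold units
            seen = {}
            for sid, unit in lo.assignment.items():
                coarse = hi.assignment[sid]
                assert seen.setdefault(unit, coarse) == coarse

    def test_unit_indices_contiguous_and_counts_monotone(self, small_matrix):
        parts = sorted(threshold_sweep(small_matrix), key=lambda p: p.threshold)
        for p in parts:
            assert sorted(set(p.assignment.values())) == list(range(p.n_units))
        counts = [p.n_units for p in parts]
        assert counts == sorted(counts, reverse=True)

    def test_cryptic_species_is_split_into_two_units(self):
        cfg = SimulationConfig(
            n_species=5, specimens_per_species=4, n_genera=3, n_families=2,
            seed=3, cryptic_species=("Gena spa",),
        )
        res = simulate(cfg)
        m = distance_matrix(res.records)
        top = threshold_sweep(m)[0]
        species = {r.specimen_id: r.morphological_label for r in res.records}
        report = split_lump_report(top, species)
        assert list(report.splits) == ["Gena spa"]
        assert len(report.splits["Gena spa"]) == 2
        assert not report.lumps


class TestSplitLump:
    def test_partition_matching_species_is_concordant(self):
        m, species = _two_species_matrix()
        top = threshold_sweep(m)[0]
        assert split_lump_report(top, species).concordant

    def test_three_species_lumped_into_one_unit(self):
        from barcodekit.gap import Partition

        p = Partition(
            assignment={"x1": 0, "y1": 0, "z1": 0, "w1": 1},
            n_units=2, threshold=0.05, gap_score=0.5,
        )
        labels = {"x1": "X", "y1": "Y", "z1": "Z", "w1": "W"}
        report = split_lump_report(p, labels)
        assert report.lumps == {0: ("X", "Y", "Z")}
        assert not report.splits

    def test_one_species_in_two_units_is_a_split(self):
        from barcodekit.gap import Partition

        p = Partition(
            assignment={"x1": 0, "x2": 1, "y1": 2},
            n_units=3, threshold=0.01, gap_score=0.2,
        )
        report = split_lump_report(p, {"x1": "X", "x2": "X", "y1": "Y"})
        assert report.splits == {"X": (0, 1)}
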