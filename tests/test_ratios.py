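import numpy as np
import pytest

from smalldecoy import (DecoyBuildSpec, DecoyMethod, ProteinDatabase,
                        ProteinRecord, UniquePeptideSet, build_small_decoy,
                        compute_db_ratio, compute_up_ratio,
                        enumerate_unique_peptides, mass_window_scan,
                        ratio_report, window_slope)
from smalldecoy.ratios import WindowSeries, apply_overlap_policy
from smalldecoy.synthetic import SimConfig, generate_protein_db


def pepset(seqs, base_mass=500.0):
    return UniquePeptideSet({s: base_mass + 7.31 * i
                             for i, s in enumerate(seqs)})


class TestUpRatio:
    def test_ratio_arithmetic(self):
        target = pepset(f"T{i}" for i in range(1000))
        decoy = pepset(f"D{i}" for i in range(250))
        assert compute_up_ratio(target, decoy) == pytest.approx(0.25)

    def test_identical_sets_give_one_with_keep_policy(self):
        s = pepset(["AAA", "BBB", "CCC"])
        assert compute_up_ratio(s, s, overlap_policy="keep") == 1.0
        # default policy credits shared peptides to the target
        assert compute_up_ratio(s, s) == 0.0

    def test_overlap_policies(self):
        target = pepset(["AAA", "BBB", "CCC", "DDD"])
        decoy = pepset(["AAA", "EEE"])
        t, d, n = apply_overlap_policy(target, decoy, "drop-from-decoy")
        assert n == 1 and len(t) == 4 and len(d) == 1
        t, d, n = apply_overlap_policy(target, decoy, "drop-from-both")
        assert len(t) == 3 and len(d) == 1
        t, d, n = apply_overlap_policy(target, decoy, "keep")
        assert len(t) == 4 and len(d) == 2

    def test_empty_target_raises(self):
        with pytest.raises(ValueError):
            compute_up_ratio(UniquePeptideSet({}), pepset(["A"]))

    def test_scale_free_under_duplication(self, synthetic_db_500):
        decoy, _ = build_small_decoy(
            synthetic_db_500, DecoyBuildSpec(DecoyMethod.REVERSE, 1.0, seed=0))
        tset = enumerate_unique_peptides(synthetic_db_500)
        dset = enumerate_unique_peptides(decoy)
        base = compute_up_ratio(tset, dset)
        # duplicating every protein adds no unique peptides on either side
        doubled_t = enumerate_unique_peptides(
            [r.sequence for r in synthetic_db_500] * 2)
        doubled_d = enumerate_unique_peptides(
            [r.sequence for r in decoy] * 2)
        assert compute_up_ratio(doubled_t, doubled_d) == pytest.approx(base)

    def test_mass_statistic_variant(self):
        target = UniquePeptideSet({"AA": 100.0, "BB": 300.0})
        decoy = UniquePeptideSet({"CC": 200.0})
        assert compute_up_ratio(target, decoy, statistic="mass") == \
            pytest.approx(0.5)


class TestDbRatio:
    def test_full_reversal_is_unity(self, synthetic_db_500):
        decoy, _ = build_small_decoy(
            synthetic_db_500, DecoyBuildSpec(DecoyMethod.REVERSE, 1.0, seed=0))
        assert compute_db_ratio(synthetic_db_500, decoy) == (1.0, 1.0)

    def test_empty_decoy_is_zero(self, synthetic_db_500):
        empty = ProteinDatabase([], is_decoy=True)
        assert compute_db_ratio(synthetic_db_500, empty) == (0.0, 0.0)

    def test_fraction_within_one_entry(self, synthetic_db_500):
        decoy, _ = build_small_decoy(
            synthetic_db_500, DecoyBuildSpec(DecoyMethod.REVERSE, 1 / 8, seed=4))
        entries, _ = compute_db_ratio(synthetic_db_500, decoy)
        assert abs(entries - 1 / 8) <= 1 / synthetic_db_500.entry_count


class TestRatioReport:
    def test_report_fields(self, synthetic_db_500):
        decoy, _ = build_small_decoy(
            synthetic_db_500, DecoyBuildSpec(DecoyMethod.REVERSE, 0.5, seed=2))
        rep = ratio_report(synthetic_db_500, decoy)
        assert 0 < rep.up_ratio < 1
        assert rep.db_ratio_entries == pytest.approx(0.5, abs=1 / 500)
        assert rep.overlap_fraction == rep.overlap_count / rep.n_target_unique
        assert rep.overlap_policy == "drop-from-decoy"

    def test_overlap_small_between_independent_databases(self):
        a = generate_protein_db(SimConfig(n_proteins=300, seed=21))
        b_src = generate_protein_db(SimConfig(n_proteins=300, seed=22))
        b = ProteinDatabase(
            [ProteinRecord("DECOY_" + r.accession, "", r.sequence)
             for r in b_src], is_decoy=True)
        rep = ratio_report(a, b)
        assert rep.overlap_fraction < 0.01


class TestMassWindows:
    def test_partition_conserves_counts(self, synthetic_db_500):
        tset = enumerate_unique_peptides(synthetic_db_500)
        decoy, _ = build_small_decoy(
            synthetic_db_500, DecoyBuildSpec(DecoyMethod.REVERSE, 0.5, seed=2))
        dset = enumerate_unique_peptides(decoy)
        series = mass_window_scan(tset, dset, 10.0)
        assert series.target_count.sum() == tset.count
        assert series.decoy_count.sum() == dset.count
        assert (series.low[1:] >= series.high[:-1] - 1e-9).all()

    def test_copy_every_fourth_peptide_gives_quarter_slope(self, synthetic_db_500):
        tset = enumerate_unique_peptides(synthetic_db_500)
        items = sorted(tset.peptides.items())
        dset = UniquePeptideSet(dict(items[::4]))
        series = mass_window_scan(tset, dset, 10.0)
        assert window_slope(series) == pytest.approx(0.25, rel=0.05)

    def test_single_peptide_sets(self):
        t = UniquePeptideSet({"AAAAAA": 1000.0})
        d = UniquePeptideSet({"CCCCCC": 1000.00001})
        series = mass_window_scan(t, d, 10.0)
        assert series.nonempty().sum() == 1

    def test_nonpositive_tolerance_rejected(self):
        t = UniquePeptideSet({"AAAAAA": 1000.0})
        with pytest.raises(ValueError):
            mass_window_scan(t, t, 0.0)


class TestWindowSlope:
    def test_exact_fit_through_origin(self):
        x = np.array([10, 20, 40, 80, 0], dtype=int)
        series = WindowSeries(
            low=np.arange(5.0), high=np.arange(1.0, 6.0),
            target_count=x, decoy_count=np.round(0.34 * x).astype(int),
            tolerance_ppm=10.0)
        series.decoy_count = (0.34 * x)  # exact points on y = 0.34 x
        assert window_slope(series) == pytest.approx(0.34)

    def test_all_zero_decoys(self):
        series = WindowSeries(
            low=np.arange(3.0), high=np.arange(1.0, 4.0),
            target_count=np.array([5, 7, 9]),
            decoy_count=np.zeros(3, dtype=int), tolerance_ppm=10.0)
        assert window_slope(series) == 0.0

    def test_too_few_windows(self):
        series = WindowSeries(
            low=np.arange(2.0), high=np.arange(1.0, 3.0),
            target_count=np.array([5, 0]),
            decoy_count=np.array([1, 0]), tolerance_ppm=10.0)
        with pytest.raises(ValueError):
            window_slope(series)
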