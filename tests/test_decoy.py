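from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import STANDARD_20
from smalldecoy import (DecoyBuildSpec, DecoyMethod, DigestParams,
                        ProteinDatabase, ProteinRecord, build_small_decoy,
                        digest_sequence, pseudo_reverse_sequence,
                        pseudo_shuffle_sequence, reverse_sequence,
                        shuffle_sequence, write_fasta)
from smalldecoy.decoy import transform_sequence

protein_strategy = st.text(alphabet=STANDARD_20, min_size=1, max_size=60)


class TestTransformations:
    def test_reverse_example(self):
        assert reverse_sequence("PEPTIDEK") == "KEDITPEP"
        assert reverse_sequence("M") == "M"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=protein_strategy)
    def test_reverse_is_involution(self, seq):
        assert reverse_sequence(reverse_sequence(seq)) == seq

    def test_pseudo_reverse_keeps_segment_termini(self):
        # segments ABCK | DEFR: non-terminal residues reversed, K/R in place
        assert pseudo_reverse_sequence("ABCKDEFR") == "CBAKFEDR"

    def test_pseudo_reverse_terminal_segment_without_kr(self):
        assert pseudo_reverse_sequence("ACDE") == "EDCA"
        assert pseudo_reverse_sequence("K") == "K"

    def test_shuffle_is_anagram_and_deterministic(self):
        seq = "PEPTIDEKAAAGGGR"
        out1 = shuffle_sequence(seq, np.random.default_rng(3))
        out2 = shuffle_sequence(seq, np.random.default_rng(3))
        assert out1 == out2
        assert Counter(out1) == Counter(seq)
        assert shuffle_sequence("AA", np.random.default_rng(0)) == "AA"

    def test_pseudo_shuffle_fixes_kr_positions(self):
        seq = "ABCKDEFR"
        out = pseudo_shuffle_sequence(seq, np.random.default_rng(1))
        assert out[3] == "K" and out[7] == "R"
        assert Counter(out[:3]) == Counter("ABC")
        assert Counter(out[4:7]) == Counter("DEF")

    def test_pseudo_shuffle_short_segments_unchanged(self):
        assert pseudo_shuffle_sequence("AK", np.random.default_rng(0)) == "AK"

    def test_pseudo_shuffle_deterministic(self):
        seq = "AAAGGGKCCCDDDRPEPTIDEK"
        assert pseudo_shuffle_sequence(seq, np.random.default_rng(9)) == \
            pseudo_shuffle_sequence(seq, np.random.default_rng(9))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=protein_strategy, method=st.sampled_from(list(DecoyMethod)))
    def test_all_methods_preserve_residue_multiset(self, seq, method):
        out = transform_sequence(seq, method, np.random.default_rng(0))
        assert Counter(out) == Counter(seq)
        assert len(out) == len(seq)

    def test_empty_sequence_rejected(self):
        for fn in (reverse_sequence, pseudo_reverse_sequence):
            with pytest.raises(ValueError):
                fn("")

    def test_pseudo_reverse_respects_proline_rule(self):
        # KP is not a cleavage point, so AKPB belongs to one segment
        params = DigestParams(suppress_before_proline=True)
        out = pseudo_reverse_sequence("AKPCDR", params)
        assert out == "DCPKAR"
        no_rule = DigestParams(suppress_before_proline=False)
        assert pseudo_reverse_sequence("AKPCDR", no_rule) == "AKDCPR"


class TestPseudoReverseMassInvariant:
    def test_internal_tryptic_masses_preserved(self):
        # plain K/R cleavage: with proline suppression the invariant is only
        # approximate (a reversed body can create or destroy a K/R-P bond)
        rng = np.random.default_rng(17)
        params = DigestParams(min_length=1, max_length=100,
                              max_missed_cleavages=0,
                              suppress_before_proline=False)
        from conftest import random_protein
        for _ in range(25):
            seq = random_protein(rng, int(rng.integers(30, 80)))
            fwd = digest_sequence(seq, params)
            rev = digest_sequence(pseudo_reverse_sequence(seq, params), params)
            # peptides come in N->C order; drop the two protein-terminal ones
            fwd_masses = [round(p.mass, 6) for p in fwd][1:-1]
            rev_masses = [round(p.mass, 6) for p in rev][1:-1]
            assert Counter(fwd_masses) == Counter(rev_masses)


class TestBuildSmallDecoy:
    def test_full_reverse_build(self, synthetic_db_500):
        spec = DecoyBuildSpec(DecoyMethod.REVERSE, fraction=1.0, seed=1)
        db, report = build_small_decoy(synthetic_db_500, spec)
        assert db.entry_count == synthetic_db_500.entry_count
        assert db.is_decoy
        originals = {r.accession: r.sequence for r in synthetic_db_500}
        for rec in db:
            src = rec.accession.removeprefix("DECOY_")
            assert rec.sequence == originals[src][::-1]
        assert report["achieved_entry_ratio"] == 1.0

    def test_fraction_entry_count_is_floor(self, synthetic_db_500):
        spec = DecoyBuildSpec(DecoyMethod.REVERSE, fraction="1/8", seed=5)
        db, report = build_small_decoy(synthetic_db_500, spec)
        assert db.entry_count == 500 // 8
        assert report["achieved_entry_ratio"] == pytest.approx(1 / 8, abs=1 / 500)

    def test_seed_reproducibility_and_variation(self, synthetic_db_500, tmp_path):
        spec = DecoyBuildSpec(DecoyMethod.SHUFFLE, fraction=0.5, seed=11)
        db1, _ = build_small_decoy(synthetic_db_500, spec)
        db2, _ = build_small_decoy(synthetic_db_500, spec)
        db3, _ = build_small_decoy(
            synthetic_db_500,
            DecoyBuildSpec(DecoyMethod.SHUFFLE, fraction=0.5, seed=12))
        write_fasta(db1, tmp_path / "a.fasta")
        write_fasta(db2, tmp_path / "b.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == \
            (tmp_path / "b.fasta").read_bytes()
        assert [r.accession for r in db1] != [r.accession for r in db3] or \
            [r.sequence for r in db1] != [r.sequence for r in db3]

    def test_residue_sampling_mode(self, synthetic_db_500):
        spec = DecoyBuildSpec(DecoyMethod.REVERSE, fraction=0.25, seed=3,
                              sample_unit="residues")
        db, report = build_small_decoy(synthetic_db_500, spec)
        assert report["achieved_residue_ratio"] <= 0.25
        assert report["achieved_residue_ratio"] == pytest.approx(
            db.residue_count / synthetic_db_500.residue_count)

    def test_invalid_fractions(self, synthetic_db_500):
        with pytest.raises(ValueError):
            DecoyBuildSpec(DecoyMethod.REVERSE, fraction=1.5, seed=0)
        tiny = ProteinDatabase([ProteinRecord("A", "", "PEPTIDEK")])
        with pytest.raises(ValueError, match="empty sample"):
            build_small_decoy(
                tiny, DecoyBuildSpec(DecoyMethod.REVERSE, fraction=0.5, seed=0))

    def test_prefix_disjointness(self, synthetic_db_500):
        spec = DecoyBuildSpec(DecoyMethod.PSEUDO_REVERSE, fraction=0.5, seed=2)
        db, _ = build_small_decoy(synthetic_db_500, spec)
        assert all(r.accession.startswith("DECOY_") for r in db)
        assert not any(r.accession.startswith("DECOY_")
                       for r in synthetic_db_500)
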