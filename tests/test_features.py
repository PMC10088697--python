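"""Descriptor-family values, normalization invariants, and encoder purity."""

import math

import numpy as np
import pytest

import il13pep as m
from il13pep.features import EncodingError, PeptideEncoder

# families that are true partitions, hence sum to 100 (PCP classes overlap)
PCT_FAMILIES = ("AAC", "DPC", "TPC", "ATC", "CTC")


class TestKmerComposition:
    def test_homopolymer_aac(self):
        v = m.kmer_composition("HHHH", 1)
        assert v["AAC_H"] == 100.0
        assert v.drop("AAC_H").eq(0).all()

    def test_single_window_tripeptide(self):
        v = m.kmer_composition("RQF", 3)
        assert v["TPC_RQF"] == 100.0
        assert v.sum() == pytest.approx(100.0)

    def test_overlapping_dipeptides(self):
        v = m.kmer_composition("ACAC", 2)
        assert v["DPC_AC"] == pytest.approx(200.0 / 3)
        assert v["DPC_CA"] == pytest.approx(100.0 / 3)

    def test_too_short_for_k_errors(self):
        with pytest.raises(EncodingError):
            m.kmer_composition("AC", 3)


class TestEntropy:
    def test_homopolymer_entropy_zero(self):
        assert m.shannon_entropy_residue("AAAA")["SER_A"] == 0.0
        assert m.sequence_entropy("AAAA") == 0.0

    def test_absent_residue_entropy_zero(self):
        assert m.shannon_entropy_residue("ACDE")["SER_I"] == 0.0

    def test_half_frequency_closed_form(self):
        assert m.shannon_entropy_residue("AC")["SER_A"] == pytest.approx(0.5)

    def test_four_equiprobable_symbols(self):
        assert m.sequence_entropy("ACDE") == pytest.approx(2.0)

    def test_sequence_entropy_equals_sum_of_residue_entropies(self):
        for pep in m.random_peptides(10, seed=3):
            assert m.sequence_entropy(pep) == pytest.approx(
                float(m.shannon_entropy_residue(pep).sum())
            )


class TestBondComposition:
    def test_single_residue_equals_table_row(self, catalog):
        chem = catalog.params["chemistry"]["W"]
        v = m.bond_composition("W", catalog)
        assert v["BTC_T"] == chem["bonds_T"]
        assert v["BTC_H"] == chem["bonds_H"]
        assert v["BTC_S"] == chem["bonds_S"]
        assert v["BTC_D"] == chem["bonds_D"]

    def test_additivity(self, catalog):
        assert (m.bond_composition("GG") == 2 * m.bond_composition("G")).all()

    def test_case_study_peptide_matches_hand_sum(self, catalog):
        seq = "ELDSFKEELDKYFKN"
        chem = catalog.params["chemistry"]
        expected = {
            kind: sum(chem[r][f"bonds_{kind}"] for r in seq)
            for kind in ("T", "H", "S", "D")
        }
        v = m.bond_composition(seq, catalog)
        for kind, val in expected.items():
            assert v[f"BTC_{kind}"] == val


class TestCtdFeatures:
    def test_single_group_peptide(self, catalog):
        # R and K are both hydrophobicity group 1: composition 100, no transitions
        v = m.ctd_features("RKRKRKRK", catalog)
        assert v["CeTD_HB1"] == 100.0
        assert v["CeTD_HB2"] == v["CeTD_HB3"] == 0.0
        assert v[["CeTD_HB_T12", "CeTD_HB_T13", "CeTD_HB_T23"]].eq(0).all()

    def test_same_group_pair_has_no_transitions(self, catalog):
        # A and V share solvent-accessibility group 1
        v = m.ctd_features("AV", catalog)
        assert v[["CeTD_SA_T12", "CeTD_SA_T13", "CeTD_SA_T23"]].eq(0).all()

    def test_distribution_quantiles_by_enumeration(self, catalog):
        # 12-mer with hydrophobicity-group-1 members (R) at positions 1, 5, 9, 12
        seq = "RAAARAAARAAR"
        positions = [i + 1 for i, ch in enumerate(seq) if ch == "R"]
        assert positions == [1, 5, 9, 12]
        L, n = len(seq), len(positions)
        v = m.ctd_features(seq, catalog)
        for q in (0, 25, 50, 75, 100):
            idx = max(1, math.ceil(q / 100 * n))
            assert v[f"CeTD_{q}_HB1"] == pytest.approx(100 * positions[idx - 1] / L)
            window = max(1, math.ceil(q / 100 * L))
            assert v[f"CeTD_{q}_p_HB1"] == sum(p <= window for p in positions)

    def test_composition_sums_to_100_per_attribute(self, catalog):
        v = m.ctd_features("ELDSFKEELDKYFKN", catalog)
        for attr in catalog.params["ctd_groups"]:
            total = sum(v[f"CeTD_{attr}{g}"] for g in (1, 2, 3))
            assert total == pytest.approx(100.0, abs=1e-9)


class TestConjointTriad:
    def test_homopolymer_single_bin(self):
        v = m.conjoint_triad("AAAA")
        assert v["CTC_111"] == 100.0
        assert (v > 0).sum() == 1

    def test_three_distinct_classes(self):
        # R->5, Q->4, F->2
        v = m.conjoint_triad("RQF")
        assert v["CTC_542"] == 100.0

    def test_sums_to_100(self):
        for pep in m.random_peptides(5, seed=4):
            assert m.conjoint_triad(pep).sum() == pytest.approx(100.0)


class TestEncode:
    def test_case_study_peptide_full_length(self, catalog):
        v = m.encode("ELDSFKEELDKYFKN", catalog)
        assert len(v) == 9151
        assert np.isfinite(v.to_numpy()).all()

    def test_encode_is_pure(self, catalog):
        a = m.encode("ELDSFKEELDKYFKN", catalog).to_numpy()
        b = m.encode("ELDSFKEELDKYFKN", catalog).to_numpy()
        assert (a == b).all()

    def test_aac_block_consistency(self, catalog):
        p = m.validate_peptide("LYRLFRKSNLKPFER")
        v = m.encode(p, catalog)
        aac = m.kmer_composition(p, 1)
        assert (v[aac.index].to_numpy() == aac.to_numpy()).all()

    def test_percentage_families_sum_to_100(self, catalog):
        slices = catalog.slices()
        for pep in m.random_peptides(8, seed=5):
            v = m.encode(pep, catalog).to_numpy()
            for fam in PCT_FAMILIES:
                assert v[slices[fam]].sum() == pytest.approx(100.0, abs=1e-9), fam

    def test_order_free_families_permutation_invariant(self, catalog):
        a = m.encode("ELDSFKEELDKYFKN", catalog)
        b = m.encode("NKFYKDLEEKFSDLE", catalog)  # a permutation
        slices = catalog.slices()
        for fam in ("AAC", "ATC", "BTC", "PCP", "SER", "SE"):
            s = slices[fam]
            assert (a.iloc[s].to_numpy() == b.iloc[s].to_numpy()).all(), fam

    def test_order_sensitive_families_change_under_permutation(self, catalog):
        a = m.encode("ACACAC", catalog)
        b = m.encode("AAACCC", catalog)
        slices = catalog.slices()
        for fam in ("DPC", "TPC"):
            s = slices[fam]
            assert not (a.iloc[s].to_numpy() == b.iloc[s].to_numpy()).all(), fam

    def test_too_short_peptide_rejected(self, catalog):
        with pytest.raises(EncodingError):
            m.encode("AC", catalog)


class TestEncodeBatch:
    def test_shape_and_order(self, catalog):
        peps = [m.Peptide(f"p{i}", s) for i, s in enumerate(["RQF", "AAAA", "ACDE"])]
        table = m.encode_batch(peps, catalog)
        assert table.shape == (3, 9151)
        assert list(table.index) == ["p0", "p1", "p2"]

    def test_empty_list_keeps_header(self, catalog):
        table = m.encode_batch([], catalog)
        assert table.shape == (0, 9151)
        assert list(table.columns) == catalog.names

    def test_batch_equals_rowwise(self, catalog):
        peps = m.random_peptides(4, seed=6)
        table = m.encode_batch(peps, catalog)
        for pep in peps:
            assert (table.loc[pep.id].to_numpy() == m.encode(pep, catalog).to_numpy()).all()

    def test_failure_names_offending_peptide(self, catalog):
        with pytest.raises(EncodingError, match="shorty"):
            m.encode_batch([m.Peptide("ok", "ACDEF"), m.Peptide("shorty", "AC")], catalog)


class TestPeptideEncoderEstimator:
    def test_transform_matrix(self, catalog):
        enc = PeptideEncoder(catalog).fit([])
        X = enc.transform(["ELDSFKEELDKYFKN", "RQFRQFRQF"])
        assert X.shape == (2, 9151)
        assert list(enc.get_feature_names_out()) == catalog.names

    def test_sklearn_params_round_trip(self, catalog):
        enc = PeptideEncoder(catalog)
        assert enc.get_params()["catalog"] is catalog
        enc.set_params(catalog=None)
        assert enc.get_params()["catalog"] is None
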