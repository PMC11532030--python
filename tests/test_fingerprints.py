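import numpy as np
import pytest

from kcatpred import (
    FingerprintConfig,
    difference_fingerprint,
    differential_fingerprint,
    parse_reaction,
    structural_fingerprint,
    substructure_multiset,
)
from kcatpred._hash import fnv1a_64, hash_to_bit
from kcatpred.errors import ChemistryError, ParameterError

from _oracles import enumerate_environments, fnv1a_64_oracle


class TestStableHash:
    @pytest.mark.parametrize("text", ["", "C", "2|CC(=O)OCC", "ünïcode"])
    def test_matches_independent_fnv1a(self, text):
        assert fnv1a_64(text) == fnv1a_64_oracle(text)

    def test_known_fnv1a_vector(self):
        # published FNV-1a test vector: "a" → 0xaf63dc4c8601ec8c
        assert fnv1a_64("a") == 0xAF63DC4C8601EC8C


class TestSubstructureMultiset:
    def test_single_atom_molecule_radius_zero(self):
        ms = substructure_multiset(["C"], {0})
        assert len(ms.entries) == 1 and list(ms.entries.values()) == [1]

    def test_smiles_rewriting_gives_identical_multiset(self):
        assert (
            substructure_multiset(["CCO"], {0, 1, 2}).entries
            == substructure_multiset(["OCC"], {0, 1, 2}).entries
        )

    def test_molecule_order_invariance(self):
        a = substructure_multiset(["CCO", "CC(=O)O"], {0, 1})
        b = substructure_multiset(["CC(=O)O", "CCO"], {0, 1})
        assert a.entries == b.entries

    def test_matches_brute_force_enumeration(self):
        mols = ["CCO", "CC(=O)O"]
        ours = substructure_multiset(mols, {0, 1}).entries
        oracle = enumerate_environments(mols, {0, 1})
        assert ours == oracle

    def test_unparseable_smiles_names_offender(self):
        with pytest.raises(ChemistryError, match="Qq"):
            substructure_multiset(["C", "Qq"], {0})


class TestStructuralFingerprint:
    def test_length_and_binary_values(self, esterification):
        fp = structural_fingerprint(parse_reaction(esterification))
        assert fp.shape == (4096,)
        assert set(np.unique(fp)) <= {0, 1}

    def test_identity_reaction_halves_equal(self):
        fp = structural_fingerprint(parse_reaction("C>>C"))
        assert (fp[:2048] == fp[2048:]).all()

    def test_reversed_reaction_swaps_halves(self, esterification):
        rxn = parse_reaction(esterification)
        fwd = structural_fingerprint(rxn)
        rev = structural_fingerprint(rxn.reversed())
        assert (fwd[:2048] == rev[2048:]).all()
        assert (fwd[2048:] == rev[:2048]).all()

    def test_popcount_matches_independent_oracle(self, esterification):
        rxn = parse_reaction(esterification)
        fp = structural_fingerprint(rxn)
        expected = np.zeros(4096, dtype=int)
        for offset, side in ((0, rxn.substrates), (2048, rxn.products)):
            for ident in enumerate_environments(side, {0, 1, 2}):
                expected[offset + fnv1a_64_oracle(ident) % 2048] = 1
        assert (fp == expected).all()

    def test_agents_are_ignored(self):
        with_agent = structural_fingerprint(parse_reaction("CCO>O>CC=O"))
        without = structural_fingerprint(parse_reaction("CCO>>CC=O"))
        assert (with_agent == without).all()


class TestDifferentialFingerprint:
    def test_identity_reaction_is_all_zero(self):
        assert differential_fingerprint(parse_reaction("C>>C")).sum() == 0

    def test_length(self, esterification):
        assert differential_fingerprint(parse_reaction(esterification)).shape == (2048,)

    def test_bits_match_signed_count_oracle(self, esterification):
        rxn = parse_reaction(esterification)
        fp = differential_fingerprint(rxn)
        sub_bins = np.zeros(2048, dtype=int)
        prod_bins = np.zeros(2048, dtype=int)
        for ident, count in enumerate_environments(rxn.substrates, {0, 1, 2}).items():
            sub_bins[fnv1a_64_oracle(ident) % 2048] += count
        for ident, count in enumerate_environments(rxn.products, {0, 1, 2}).items():
            prod_bins[fnv1a_64_oracle(ident) % 2048] += count
        assert (fp == (prod_bins != sub_bins).astype(int)).all()

    def test_multiplicity_sensitivity(self):
        # 2 ethanol → 1 ethanol: sets agree, counts differ
        fp = differential_fingerprint(parse_reaction("CCO.CCO>>CCO"))
        assert fp.sum() > 0


class TestDifferenceFingerprint:
    def test_identity_reaction_is_all_zero(self):
        assert difference_fingerprint(parse_reaction("C>>C")).sum() == 0

    def test_length(self, esterification):
        assert difference_fingerprint(parse_reaction(esterification)).shape == (2048,)

    def test_set_symmetric_difference_oracle(self, esterification):
        rxn = parse_reaction(esterification)
        fp = difference_fingerprint(rxn)
        sub = set(enumerate_environments(rxn.substrates, {0, 1, 2}))
        prod = set(enumerate_environments(rxn.products, {0, 1, 2}))
        expected = np.zeros(2048, dtype=int)
        for ident in sub ^ prod:
            expected[fnv1a_64_oracle(ident) % 2048] = 1
        assert (fp == expected).all()

    def test_multiplicity_insensitive(self):
        # same identifier sets on both sides → zero despite count change
        assert difference_fingerprint(parse_reaction("CCO.CCO>>CCO")).sum() == 0


class TestFingerprintConfig:
    def test_non_power_of_two_bits_rejected(self):
        with pytest.raises(ParameterError):
            FingerprintConfig(bits_per_side=1000)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ParameterError):
            FingerprintConfig(radius=0)

    def test_custom_sizes_respected(self, esterification):
        cfg = FingerprintConfig(bits_per_side=512, diff_bits=256, drfp_bits=128)
        rxn = parse_reaction(esterification)
        assert structural_fingerprint(rxn, cfg).shape == (1024,)
        assert differential_fingerprint(rxn, cfg).shape == (256,)
        assert difference_fingerprint(rxn, cfg).shape == (128,)


@pytest.mark.parametrize(
    "scheme", [structural_fingerprint, differential_fingerprint, difference_fingerprint]
)
def test_all_schemes_invariant_to_order_and_smiles_form(scheme, esterification):
    a = parse_reaction(esterification)
    b = parse_reaction("OCC.CC(=O)O>>O.CC(=O)OCC")  # reordered, rewritten
    assert (scheme(a) == scheme(b)).all()
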