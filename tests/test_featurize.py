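import numpy as np
import pandas as pd
import pytest

from dyesol import (
    load_descriptor_table,
    lookup_solvent,
    mol_to_graph,
    morgan_fingerprint,
    nearest_neighbor_similarity,
    rdkit_fingerprint,
    tanimoto,
)
from dyesol.curation import InvalidSmilesError
from dyesol.featurize import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, BitFingerprint


class TestMolGraph:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_bonds",
        [("C", 1, 0), ("CC", 2, 2), ("c1ccccc1", 6, 12)],
    )
    def test_counts(self, smiles, n_atoms, n_bonds):
        g = mol_to_graph(smiles)
        assert (g.n_atoms, g.n_bonds) == (n_atoms, n_bonds)
        assert g.atom_features.shape == (n_atoms, ATOM_FEATURE_DIM)
        assert g.bond_features.shape == (n_bonds, BOND_FEATURE_DIM)

    def test_reverse_is_involution(self):
        g = mol_to_graph("c1ccc2cc3ccccc3cc2c1")
        assert np.array_equal(g.rev[g.rev], np.arange(g.n_bonds))
        assert np.array_equal(g.src[g.rev], g.dst)
        assert np.array_equal(g.dst[g.rev], g.src)

    def test_spelling_invariance(self):
        g1, g2 = mol_to_graph("OCC"), mol_to_graph("CCO")
        assert np.array_equal(g1.atom_features, g2.atom_features)
        assert np.array_equal(g1.bond_features, g2.bond_features)

    def test_invalid_smiles_raises(self):
        with pytest.raises(InvalidSmilesError):
            mol_to_graph("C1CC")


class TestFingerprints:
    def test_morgan_spelling_invariance(self):
        assert np.array_equal(
            morgan_fingerprint("CCO").bits, morgan_fingerprint("OCC").bits
        )

    def test_morgan_default_parameters(self):
        fp = morgan_fingerprint("c1ccccc1O")
        assert fp.nbits == 256 and fp.radius == 4

    def test_methane_popcount_golden(self):
        # frozen from the hashing scheme: methane sets exactly one bit
        assert morgan_fingerprint("C").popcount() == 1

    def test_self_similarity_is_one(self):
        fp = morgan_fingerprint("c1ccc2cc3ccccc3cc2c1")
        assert tanimoto(fp, fp) == 1.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], 1 / 3),
            ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),
            ([0, 0, 0, 0], [0, 0, 0, 0], 1.0),  # two empty vectors by convention
        ],
    )
    def test_tanimoto_hand_values(self, a, b, expected):
        fa = BitFingerprint(np.array(a, dtype=np.uint8), 4, 0)
        fb = BitFingerprint(np.array(b, dtype=np.uint8), 4, 0)
        assert tanimoto(fa, fb) == pytest.approx(expected)

    def test_tanimoto_length_mismatch(self):
        fa = BitFingerprint(np.zeros(4, dtype=np.uint8), 4, 0)
        fb = BitFingerprint(np.zeros(8, dtype=np.uint8), 8, 0)
        with pytest.raises(ValueError):
            tanimoto(fa, fb)

    def test_rdkit_fingerprint_default_size(self):
        assert rdkit_fingerprint("c1ccccc1").nbits == 2048


class TestNearestNeighbor:
    def test_identical_pair_within_set(self):
        fps = [morgan_fingerprint("CCO"), morgan_fingerprint("OCC")]
        best, mean = nearest_neighbor_similarity(fps)
        assert np.allclose(best, 1.0) and mean == 1.0

    def test_singleton_within_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_neighbor_similarity([morgan_fingerprint("C")])

    def test_matches_bruteforce(self):
        smiles = ["c1ccccc1", "Cc1ccccc1", "CCO", "c1ccc2ccccc2c1", "CC(C)O"]
        fps = [rdkit_fingerprint(s) for s in smiles]
        best, mean = nearest_neighbor_similarity(fps)
        expected = []
        for i in range(len(fps)):
            expected.append(
                max(tanimoto(fps[i], fps[j]) for j in range(len(fps)) if j != i)
            )
        assert np.allclose(best, expected)
        assert mean == pytest.approx(float(np.mean(expected)))

    def test_cross_set_mode(self):
        q = [rdkit_fingerprint("Cc1ccccc1")]
        ref = [rdkit_fingerprint("Cc1ccccc1"), rdkit_fingerprint("CCO")]
        best, _ = nearest_neighbor_similarity(q, ref)
        assert best[0] == 1.0  # molecule present verbatim in reference


class TestSolventDescriptors:
    def test_packaged_tables_load_and_have_right_width(self):
        cgsd = load_descriptor_table(None, "cgsd")
        minn = load_descriptor_table(None, "minnesota")
        assert cgsd.dim == 5 and minn.dim == 7
        for vec in cgsd.entries.values():
            assert vec.shape == (5,)
        for vec in minn.entries.values():
            assert vec.shape == (7,)

    def test_lookup_by_any_spelling(self):
        table = load_descriptor_table(None, "cgsd")
        a = lookup_solvent("C1CCOC1", table)
        b = lookup_solvent("O1CCCC1", table)
        assert a is not None and np.array_equal(a, b)

    def test_missing_is_a_value_not_an_exception(self):
        table = load_descriptor_table(None, "cgsd")
        assert lookup_solvent("CCCCCCCCCCCC", table) is None

    def test_incomplete_entry_rejected(self):
        df = pd.DataFrame(
            {
                "solvent_smiles": ["O"],
                "et30": [63.1],
                "sa": [1.0],
                "sb": [0.0],
                "sdp": [np.nan],
                "sp": [0.7],
            }
        )
        with pytest.raises(ValueError):
            load_descriptor_table(df, "cgsd")
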