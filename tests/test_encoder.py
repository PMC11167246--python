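import numpy as np
import pytest

from ican import chem_io, encoder
from ican.encoder import (
    EncodingConfig,
    build_alphabet,
    encode_dataset,
    encode_molecule,
    flatten_and_pad,
    unflatten,
)
from ican.fixtures import gen_random_peptides


class TestBuildAlphabet:
    def test_mode1_is_protein_big_five(self):
        assert build_alphabet(1).symbols == ("H", "C", "N", "O", "S")

    def test_mode2_drops_hydrogen(self):
        assert build_alphabet(2).symbols == ("C", "N", "O", "S")

    def test_mode3_is_data_driven(self, phenol):
        assert build_alphabet(3, [phenol]).symbols == ("H", "C", "O")

    def test_mode3_without_data_raises(self):
        with pytest.raises(ValueError):
            build_alphabet(3)

    def test_invalid_mode_raises(self):
        with pytest.raises(ValueError):
            build_alphabet(4)


class TestEncodeMolecule:
    def test_methane_single_column(self):
        g = chem_io.parse_smiles("C")
        arr = encode_molecule(g, build_alphabet(1), levels=1)
        assert arr.values.shape == (5, 1)
        np.testing.assert_array_equal(arr.values[:, 0], [4, 0, 0, 0, 0])

    def test_phenol_mode1_level1(self, phenol):
        arr = encode_molecule(phenol, build_alphabet(1), levels=1)
        assert arr.values.shape == (5, 6)
        oh_col = [0, 2, 0, 1, 0]
        plain_col = [1, 2, 0, 0, 0]
        np.testing.assert_array_equal(arr.values[:, 3], oh_col)
        for j in [0, 1, 2, 4, 5]:
            np.testing.assert_array_equal(arr.values[:, j], plain_col)

    def test_ethane_two_levels(self):
        g = chem_io.parse_smiles("CC")
        arr = encode_molecule(g, build_alphabet(1), levels=2)
        expected = [3, 1, 0, 0, 0, 3, 0, 0, 0, 0]
        np.testing.assert_array_equal(arr.values[:, 0], expected)
        np.testing.assert_array_equal(arr.values[:, 1], expected)

    def test_cyclohexane_symmetric_columns(self, molecules):
        g = molecules["cyclohexane"][0]
        arr = encode_molecule(g, build_alphabet(1), levels=1)
        for j in range(6):
            np.testing.assert_array_equal(arr.values[:, j], [2, 2, 0, 0, 0])

    def test_elements_outside_alphabet_not_counted(self, molecules):
        g = molecules["ethanethiol"][0]  # CCS
        arr = encode_molecule(g, build_alphabet(2), levels=1)
        # mode 2 has no H row; sulfur-adjacent carbon column is C=1, S=1
        assert arr.values.shape == (4, 2)
        np.testing.assert_array_equal(arr.values[:, 1], [1, 0, 0, 1])

    def test_mode3_level1_block_sums_to_degree(self, molecules):
        """Conservation: with the data-driven alphabet every neighbor is
        counted, so each level-1 column block sums to the carbon's degree."""
        graphs = [g for g, _ in molecules.values()]
        alphabet = build_alphabet(3, graphs)
        from ican.backbone import index_carbons

        for (name, (g, _)) in zip(molecules, molecules.values()):
            arr = encode_molecule(g, alphabet, levels=2)
            idx = index_carbons(g)
            level1 = arr.values[: len(alphabet), :]
            for j, c in enumerate(idx):
                assert level1[:, j].sum() == g.graph.degree[c], (name, j)

    def test_levels_monotonicity(self, molecules):
        """Adding a level leaves all previously computed rows unchanged."""
        alphabet = build_alphabet(1)
        for name, (g, _) in molecules.items():
            a2 = encode_molecule(g, alphabet, levels=2)
            a3 = encode_molecule(g, alphabet, levels=3)
            np.testing.assert_array_equal(a3.values[:10, :], a2.values, err_msg=name)


class TestFlattenAndPad:
    def test_single_array_no_padding(self):
        g = chem_io.parse_smiles("CC")
        arr = encode_molecule(g, build_alphabet(1), levels=1)
        ds = flatten_and_pad([arr])
        assert ds.matrix.shape == (1, 10)
        np.testing.assert_array_equal(ds.matrix[0], arr.values.flatten(order="F"))

    def test_padding_to_max_carbons(self):
        alphabet = build_alphabet(1)
        a2 = encode_molecule(chem_io.parse_smiles("CC"), alphabet, levels=1)
        a3 = encode_molecule(chem_io.parse_smiles("CCC"), alphabet, levels=1)
        ds = flatten_and_pad([a2, a3])
        assert ds.matrix.shape == (2, 15)
        np.testing.assert_array_equal(ds.matrix[0, 10:], np.zeros(5))
        assert ds.carbon_counts == [2, 3]

    def test_unflatten_round_trip(self):
        alphabet = build_alphabet(1)
        a2 = encode_molecule(chem_io.parse_smiles("CC"), alphabet, levels=2)
        a4 = encode_molecule(chem_io.parse_smiles("CCCC"), alphabet, levels=2)
        ds = flatten_and_pad([a2, a4])
        back = unflatten(ds.matrix[0], ds.layout)
        np.testing.assert_array_equal(back[:, :2], a2.values)
        np.testing.assert_array_equal(back[:, 2:], np.zeros((10, 2)))

    def test_mixed_alphabets_raise(self, phenol):
        a1 = encode_molecule(phenol, build_alphabet(1), levels=1)
        a2 = encode_molecule(phenol, build_alphabet(2), levels=1)
        with pytest.raises(ValueError):
            flatten_and_pad([a1, a2])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            flatten_and_pad([])


class TestEncodeDataset:
    def test_diglycine_feature_count(self):
        ds = encode_dataset(
            [chem_io.FastaRecord("p1", "GG")], EncodingConfig(mode=1, levels=2), "fasta"
        )
        # glycylglycine has 4 carbons; 5 elements x 2 levels x 4 carbons
        assert ds.matrix.shape == (1, 40)

    def test_deterministic(self):
        records = gen_random_peptides(10, (4, 8), seed=5)
        cfg = EncodingConfig(mode=3, levels=2)
        d1 = encode_dataset(records, cfg, "fasta")
        d2 = encode_dataset(records, cfg, "fasta")
        np.testing.assert_array_equal(d1.matrix, d2.matrix)
        assert d1.layout == d2.layout

    def test_mixed_fasta_and_smiles(self):
        records = [chem_io.FastaRecord("p1", "G"), ("phenol", "C1=CC=C(C=C1)O")]
        ds = encode_dataset(records, EncodingConfig(mode=1, levels=1), "smiles")
        assert ds.matrix.shape[0] == 2
        assert ds.layout.max_carbons == 6

    def test_failures_collected_not_fatal(self):
        with pytest.warns(UserWarning, match="bad"):
            ds = encode_dataset(
                [("ok", "CC"), ("bad", "not_smiles")], EncodingConfig(mode=1, levels=1)
            )
        assert ds.names == ["ok"]

    def test_all_failures_abort(self):
        with pytest.raises(chem_io.ParseError, match="all 1 records failed"):
            encode_dataset([("bad", "][")], EncodingConfig())

    def test_save_load_round_trip(self, tmp_path):
        records = gen_random_peptides(5, (3, 6), seed=11)
        ds = encode_dataset(records, EncodingConfig(mode=1, levels=2), "fasta")
        ds.save(tmp_path / "enc")
        loaded = encoder.EncodedDataset.load(tmp_path / "enc")
        np.testing.assert_array_equal(loaded.matrix, ds.matrix)
        assert loaded.layout == ds.layout
        assert loaded.names == [r.identifier for r in records]

    def test_unbranched_peptide_column_count_matches_formula(self):
        """Column count equals the carbon count of the assembled SMILES."""
        from ican.fixtures import AMINO_ACID_FORMULAS

        seq = "GAVLM"
        expected_carbons = sum(AMINO_ACID_FORMULAS[r]["C"] for r in seq)
        ds = encode_dataset([chem_io.FastaRecord("p", seq)], EncodingConfig(1, 1), "fasta")
        assert ds.layout.max_carbons == expected_carbons
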