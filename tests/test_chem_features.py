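"""Descriptor computations against brute-force and hand-derived oracles."""

import itertools

import numpy as np
import networkx as nx
import pytest
from rdkit import Chem

from combosyn.chem_features import (
    FeatureConfig,
    cluster_drugs,
    featurize_drug,
    featurize_library,
    isida_path_fragments,
    maccs_features,
    morgan_features,
    parse_structures,
    physchem_features,
    similarity_matrix,
    sirms_simplex_fragments,
    tanimoto,
)


def _reordered(mol_id, smiles, perm_seed):
    """Same structure written from a different atom ordering."""
    rd = Chem.MolFromSmiles(smiles)
    order = list(range(rd.GetNumAtoms()))
    rng = np.random.default_rng(perm_seed)
    rng.shuffle(order)
    rd2 = Chem.RenumberAtoms(rd, [int(i) for i in order])
    out, _ = parse_structures(f"{Chem.MolToSmiles(rd2, canonical=False)} {mol_id}")
    return out[0]


class TestParsing:
    def test_ethanol_graph(self, mols):
        m = mols["ethanol"]
        assert m.n_atoms == 3
        assert sorted(sym for _, _, sym in m.bonds) == ["-", "-"]

    def test_benzene_aromatic(self, mols):
        m = mols["benzene"]
        assert all(arom for _, arom, _ in m.atoms)
        assert all(sym == ":" for _, _, sym in m.bonds)
        assert len(m.bonds) == 6

    def test_bad_record_skipped_batch_continues(self):
        out, skipped = parse_structures("CCO ok\nnot_a_smiles bad\nCCC ok2")
        assert [m.id for m in out] == ["ok", "ok2"]
        assert len(skipped) == 1 and skipped[0][0] == "bad"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            parse_structures("")

    def test_sdf_roundtrip(self, mols):
        rd = Chem.MolFromSmiles(mols["aspirin"].source)
        rd.SetProp("_Name", "aspirin")
        out, skipped = parse_structures(Chem.MolToMolBlock(rd) + "$$$$\n", fmt="sdf")
        assert not skipped
        assert out[0].n_atoms == mols["aspirin"].n_atoms


class TestMorgan:
    def test_length_and_binary(self, mols):
        fb = morgan_features(mols["aspirin"])
        assert len(fb.values) == 256
        assert set(np.unique(fb.values)) <= {0.0, 1.0}

    def test_binarized_counts_equal_binary(self, mols):
        for m in mols.values():
            counted = morgan_features(m, counted=True)
            binary = morgan_features(m, counted=False)
            np.testing.assert_array_equal(np.sign(counted.values), binary.values)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_atom_order_invariance(self, mols, seed):
        m = mols["ibuprofen"]
        m2 = _reordered("ibu2", m.source, seed)
        np.testing.assert_array_equal(
            morgan_features(m, counted=True).values,
            morgan_features(m2, counted=True).values,
        )


class TestMaccs:
    def test_length_166(self, mols):
        assert len(maccs_features(mols["aspirin"]).values) == 166

    def test_benzene_aromatic_key_set(self, mols):
        fb = maccs_features(mols["benzene"])
        on = {fid for fid, v in zip(fb.feature_ids, fb.values) if v}
        assert 162 in on  # the "is aromatic" key

    def test_methane_no_multiatom_keys(self, mols):
        fb = maccs_features(mols["methane"])
        # a lone carbon can satisfy at most trivial single-atom patterns
        assert fb.values.sum() <= 1


class TestIsidaPaths:
    def test_propane_hand_counts(self, mols):
        fb = isida_path_fragments(mols["propane"])
        assert dict(zip(fb.feature_ids, fb.values)) == {"C-C": 2.0, "C-C-C": 1.0}

    def test_single_atom_empty(self, mols):
        fb = isida_path_fragments(mols["methane"])
        assert len(fb.values) == 0

    def test_benzene_aromatic_sequences(self, mols):
        fb = isida_path_fragments(mols["benzene"])
        counts = dict(zip(fb.feature_ids, fb.values))
        assert counts["C:C"] == 6.0
        assert counts["C:C:C"] == 6.0
        assert counts["C:C:C:C:C:C"] == 6.0

    @staticmethod
    def nx_path_oracle(mol, lo=2, hi=6):
        """Independent enumeration of all undirected simple paths."""
        g = nx.Graph()
        for i, (sym, _, _) in enumerate(mol.atoms):
            g.add_node(i, sym=sym)
        for i, j, sym in mol.bonds:
            g.add_edge(i, j, sym=sym)
        counts = {}
        for a, b in itertools.combinations(g.nodes, 2):
            for path in nx.all_simple_paths(g, a, b, cutoff=hi - 1):
                if not lo <= len(path) <= hi:
                    continue
                labs = [g.nodes[n]["sym"] for n in path]
                bonds = [g.edges[path[k], path[k + 1]]["sym"] for k in range(len(path) - 1)]
                fwd = labs[0] + "".join(s + l for s, l in zip(bonds, labs[1:]))
                rev = labs[-1] + "".join(s + l for s, l in zip(bonds[::-1], labs[::-1][1:]))
                frag = min(fwd, rev)
                counts[frag] = counts.get(frag, 0) + 1
        return counts

    def test_matches_exhaustive_oracle(self, mols):
        for m in mols.values():
            if m.n_atoms > 12:
                continue
            fb = isida_path_fragments(m)
            got = {fid: int(v) for fid, v in zip(fb.feature_ids, fb.values)}
            assert got == self.nx_path_oracle(m), m.id

    @pytest.mark.parametrize("seed", [1, 2])
    def test_atom_order_invariance(self, mols, seed):
        m = mols["tryptophan"]
        m2 = _reordered("trp2", m.source, seed)
        a, b = isida_path_fragments(m), isida_path_fragments(m2)
        assert dict(zip(a.feature_ids, a.values)) == dict(zip(b.feature_ids, b.values))


class TestSirmsSimplexes:
    def test_nbutane_single_chain_fragment(self, mols):
        fb = sirms_simplex_fragments(mols["nbutane"])
        assert dict(zip(fb.feature_ids, fb.values)) == {"C,C,C,C|--..-.": 1.0}

    def test_isobutane_star_distinct_from_chain(self, mols):
        fb = sirms_simplex_fragments(mols["isobutane"])
        assert dict(zip(fb.feature_ids, fb.values)) == {"C,C,C,C|---...": 1.0}

    def test_under_four_atoms_empty(self, mols):
        assert len(sirms_simplex_fragments(mols["propane"]).values) == 0

    def test_counts_sum_to_n_choose_4(self, mols):
        import math

        for m in mols.values():
            fb = sirms_simplex_fragments(m)
            assert fb.values.sum() == math.comb(m.n_atoms, 4), m.id

    def test_atom_cap_guard(self, mols):
        cfg = FeatureConfig(sirms_atom_cap=5)
        with pytest.raises(ValueError, match="cap"):
            sirms_simplex_fragments(mols["aspirin"], cfg)

    def test_atom_order_invariance(self, mols):
        m = mols["ibuprofen"]
        m2 = _reordered("ibu2", m.source, 7)
        a, b = sirms_simplex_fragments(m), sirms_simplex_fragments(m2)
        assert dict(zip(a.feature_ids, a.values)) == dict(zip(b.feature_ids, b.values))


class TestPhyschem:
    def test_seven_features(self, mols):
        fb = physchem_features(mols["aspirin"])
        assert len(fb.values) == 7
        assert fb.feature_ids[0] == "tpsa"

    def test_benzene_values(self, mols):
        fb = physchem_features(mols["benzene"])
        vals = dict(zip(fb.feature_ids, fb.values))
        assert vals["tpsa"] == 0.0
        assert vals["n_aromatic_rings"] == 1
        assert vals["n_aliphatic_rings"] == 0
        assert vals["n_hbond_donors"] == 0

    def test_methane_zeros(self, mols):
        fb = physchem_features(mols["methane"])
        vals = dict(zip(fb.feature_ids, fb.values))
        for k in ("n_aliphatic_rings", "n_aromatic_rings", "n_hbond_donors", "n_hbond_acceptors"):
            assert vals[k] == 0


class TestFeaturize:
    def test_mfpc_physchem_length(self, mols):
        cfg = FeatureConfig(blocks=("mfpc", "physchem"))
        df = featurize_drug(mols["aspirin"], cfg)
        assert len(df.vector) == 263

    def test_maccs_only_length(self, mols):
        df = featurize_drug(mols["aspirin"], FeatureConfig(blocks=("maccs",)))
        assert len(df.vector) == 166

    def test_shared_vocabulary_equal_lengths(self, mols):
        cfg = FeatureConfig(blocks=("isida", "sirms", "physchem"))
        feats, vocabs = featurize_library(list(mols.values()), cfg)
        lengths = {len(f.vector) for f in feats.values()}
        assert len(lengths) == 1
        assert lengths.pop() == len(vocabs["isida"]) + len(vocabs["sirms"]) + 7

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(blocks=("mfp", "nope"))


class TestTanimoto:
    def test_identity_is_one(self):
        v = np.array([1.0, 2.0, 0.0])
        assert tanimoto(v, v) == 1.0

    def test_hand_case_one_third(self):
        assert tanimoto([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_disjoint_and_degenerate(self):
        assert tanimoto([1, 0], [0, 1]) == 0.0
        assert tanimoto([0, 0], [0, 0]) == 0.0

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = rng.integers(0, 5, size=8).astype(float)
            b = rng.integers(0, 5, size=8).astype(float)
            s = tanimoto(a, b)
            assert s == tanimoto(b, a)
            assert 0.0 <= s <= 1.0
            if not np.array_equal(a, b):
                assert s < 1.0 or np.array_equal(np.minimum(a, b), np.maximum(a, b))

    def test_errors(self):
        with pytest.raises(ValueError):
            tanimoto([1, 2], [1])
        with pytest.raises(ValueError):
            tanimoto([-1, 0], [0, 1])


class TestClustering:
    def test_identical_structures_cluster(self):
        out, _ = parse_structures("CCO a\nCCO b\nc1ccccc1 c")
        feats, _ = featurize_library(out, FeatureConfig(blocks=("mfpc",)))
        _, res = cluster_drugs(list(feats.values()), threshold=0.8)
        assert res["clusters"] == [["a", "b"]]

    def test_dissimilar_structures_no_clusters(self, mols):
        picks = [mols["benzene"], mols["sorbitol"], mols["tryptophan"]]
        feats, _ = featurize_library(picks, FeatureConfig(blocks=("mfpc",)))
        sim = similarity_matrix(list(feats.values()))
        assert (sim[np.triu_indices(3, k=1)] < 0.8).all()
        _, res = cluster_drugs(list(feats.values()), threshold=0.8)
        assert res["clusters"] == []

    def test_planted_homologous_series_recovered(self):
        out, _ = parse_structures(
            "CCCCCC hexA\nCCCCCCC hexB\nCCCCCCCC hexC\n"
            "c1ccccc1O phenA\nc1ccccc1N phenB\n"
            "NC(Cc1c[nH]c2ccccc12)C(=O)O trp\nOCC(O)C(O)C(O)C(O)CO sorb"
        )
        feats, _ = featurize_library(out, FeatureConfig(blocks=("mfpc",)))
        _, res = cluster_drugs(list(feats.values()), threshold=0.6)
        assert ["hexA", "hexB", "hexC"] in res["clusters"]

    def test_too_few_drugs(self, mols):
        feats, _ = featurize_library([mols["benzene"]], FeatureConfig(blocks=("mfpc",)))
        with pytest.raises(ValueError):
            cluster_drugs(list(feats.values()))
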