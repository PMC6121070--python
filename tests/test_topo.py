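import math

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from arscreen import topo
from arscreen.chemio import Molecule, topological_distance_matrix
from arscreen.properties import atom_weights


def reorder(molecule: Molecule, seed: int = 5) -> Molecule:
    """Same chemical graph, shuffled atom numbering."""
    rng = np.random.default_rng(seed)
    perm = [int(i) for i in rng.permutation(molecule.heavy.GetNumAtoms())]
    return Molecule(Chem.RenumberAtoms(molecule.heavy, perm), molecule.mol_id + "_perm")


def nx_graph(heavy):
    g = nx.Graph()
    g.add_nodes_from(range(heavy.GetNumAtoms()))
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in heavy.GetBonds())
    return g


class TestGeary:
    def test_two_atom_molecule_is_one(self, make_mol):
        # A=2: numerator (w1-w2)^2/2 equals the sample variance exactly
        for scheme in ("m", "v", "e", "p"):
            assert topo.geary_autocorrelation(make_mol("CN"), 1, scheme).value == pytest.approx(1.0)

    def test_zero_variance_on_all_carbon(self, make_mol):
        v = topo.geary_autocorrelation(make_mol("c1ccc2ccccc2c1"), 1, "v")
        assert not v.computed and v.reason == "zero-variance"

    def test_no_pairs_at_large_lag(self, make_mol):
        v = topo.geary_autocorrelation(make_mol("CCO"), 9, "e")
        assert not v.computed and v.reason == "no-pairs-at-lag"

    @pytest.mark.parametrize("lag", [1, 2, 3])
    def test_matches_double_loop_oracle(self, oracle_molecules, lag):
        for mol in oracle_molecules:
            heavy = mol.heavy
            a = heavy.GetNumAtoms()
            if a < 2:
                continue
            w = atom_weights(heavy, "e")
            if np.var(w) == 0:
                continue
            sp = dict(nx.all_pairs_shortest_path_length(nx_graph(heavy)))
            num, npairs = 0.0, 0
            for i in range(a):
                for j in range(a):
                    if i != j and sp[i].get(j) == lag:
                        num += (w[i] - w[j]) ** 2
                        npairs += 1
            if npairs == 0:
                assert not topo.geary_autocorrelation(mol, lag, "e").computed
                continue
            expect = (num / (2 * npairs)) / (np.sum((w - w.mean()) ** 2) / (a - 1))
            got = topo.geary_autocorrelation(mol, lag, "e").value
            assert got == pytest.approx(expect, rel=1e-12)

    def test_reorder_invariance(self, make_mol):
        m = make_mol("CC(=O)Nc1ccc(F)cc1")
        for lag in (1, 2, 3):
            a = topo.geary_autocorrelation(m, lag, "v").value
            b = topo.geary_autocorrelation(reorder(m), lag, "v").value
            assert a == pytest.approx(b, rel=1e-12)

    def test_expectation_one_for_iid_weights(self, make_mol):
        # Geary statistic has expectation 1 under spatial randomness
        rng = np.random.default_rng(0)
        heavy = make_mol("CCCCCCCCCC").heavy
        d = np.asarray(Chem.GetDistanceMatrix(heavy)).astype(int)
        a = heavy.GetNumAtoms()
        vals = []
        for _ in range(4000):
            w = rng.standard_normal(a)
            mask = d == 2
            num = ((w[:, None] - w[None, :]) ** 2)[mask].sum() / (2 * mask.sum())
            var = np.sum((w - w.mean()) ** 2) / (a - 1)
            vals.append(num / var)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestBurden:
    def test_ethane_closed_form(self, make_mol):
        # 2x2 matrix [[1, 0.11], [0.11, 1]]: eigenvalues 1 +/- 0.11
        v = topo.burden_eigenvalue(make_mol("CC"), 1, "m")
        assert v.value == pytest.approx(1.11, abs=1e-12)

    def test_rank_exceeding_atoms_missing(self, make_mol):
        v = topo.burden_eigenvalue(make_mol("CCO"), 7, "p")
        assert not v.computed and v.reason == "too-few-atoms"

    def test_full_spectrum_matches_explicit_matrix(self, oracle_molecules):
        for mol in oracle_molecules:
            a = mol.num_heavy_atoms
            if a < 2:
                continue
            b = topo.burden_matrix(mol, "p")
            assert np.allclose(b, b.T)
            spectrum = np.sort(np.linalg.eigvalsh(b))[::-1]
            for rank in range(1, a + 1):
                got = topo.burden_eigenvalue(mol, rank, "p").value
                assert got == pytest.approx(spectrum[rank - 1], rel=1e-12)

    def test_matrix_conventions(self, make_mol):
        # propane: terminal bonds get the +0.01 correction, non-bonded 0.001
        b = topo.burden_matrix(make_mol("CCC"), "m")
        assert b[0, 1] == pytest.approx(0.11)
        assert b[0, 2] == pytest.approx(0.001)
        # benzene: aromatic order 1.5, no terminal atoms
        b6 = topo.burden_matrix(make_mol("c1ccccc1"), "m")
        assert b6[0, 1] == pytest.approx(0.15)


class TestInformationContent:
    def test_methane_order1(self, make_mol):
        v = topo.information_content(make_mol("C"), 1)
        expect = -(1 / 5) * math.log2(1 / 5) - (4 / 5) * math.log2(4 / 5)
        assert v.value == pytest.approx(expect, abs=1e-9)

    def test_benzene_order0_one_bit(self, make_mol):
        assert topo.information_content(make_mol("c1ccccc1"), 0).value == pytest.approx(1.0)

    @pytest.mark.parametrize("smiles", ["CCO", "NCC(=O)O", "c1ccncc1", "CC(C)CC"])
    def test_nondecreasing_in_order(self, make_mol, smiles):
        m = make_mol(smiles)
        vals = [topo.information_content(m, k).value for k in range(6)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_bounded_by_log_atom_count(self, oracle_molecules):
        for mol in oracle_molecules:
            total = mol.with_hs.GetNumAtoms()
            for k in (1, 5):
                v = topo.information_content(mol, k).value
                assert 0.0 <= v <= math.log2(total) + 1e-12


class TestIVDE:
    def test_cyclohexane_zero(self, make_mol):
        assert topo.vertex_degree_information(make_mol("C1CCCCC1")).value == pytest.approx(0.0)

    def test_butane_one_bit(self, make_mol):
        assert topo.vertex_degree_information(make_mol("CCCC")).value == pytest.approx(1.0)

    def test_matches_degree_histogram_oracle(self, oracle_molecules):
        from collections import Counter
        for mol in oracle_molecules:
            heavy = mol.heavy
            counts = Counter(len(a.GetNeighbors()) for a in heavy.GetAtoms())
            a = heavy.GetNumAtoms()
            expect = -sum((c / a) * math.log2(c / a) for c in counts.values())
            assert topo.vertex_degree_information(mol).value == pytest.approx(expect, abs=1e-12)


class TestC009:
    def test_methane_zero(self, make_mol):
        assert topo.atom_centered_fragment_C009(make_mol("C")).value == 0

    def test_dichloroethane_one(self, make_mol):
        assert topo.atom_centered_fragment_C009(make_mol("CC(Cl)Cl")).value == 1

    def test_reorder_invariant(self, make_mol):
        m = make_mol("CC(Cl)C(F)(Cl)CC(Br)Br")
        assert (topo.atom_centered_fragment_C009(m).value
                == topo.atom_centered_fragment_C009(reorder(m)).value)


class TestPairFrequency:
    def test_absent_element(self, make_mol):
        assert topo.pair_frequency(make_mol("NCCCCC"), "N", "F", 5).value == 0

    def test_single_path(self, make_mol):
        assert topo.pair_frequency(make_mol("NCCCCF"), "N", "F", 5).value == 1

    def test_matches_shortest_path_oracle(self, oracle_molecules):
        for mol in oracle_molecules:
            heavy = mol.heavy
            symbols = [a.GetSymbol() for a in heavy.GetAtoms()]
            sp = dict(nx.all_pairs_shortest_path_length(nx_graph(heavy)))
            for pair, dist in [(("N", "O"), 2), (("C", "O"), 1), (("C", "F"), 2)]:
                expect = sum(
                    1
                    for i in range(len(symbols))
                    for j in range(i + 1, len(symbols))
                    if sp[i].get(j) == dist and {symbols[i], symbols[j]} == set(pair)
                )
                got = topo.pair_frequency(mol, pair[0], pair[1], dist).value
                assert got == expect


class TestMLOGP:
    def test_benzene_term_counts(self, make_mol):
        t = topo.mlogp_terms(make_mol("c1ccccc1"))
        assert t["CX"] == 6.0 and t["NO"] == 0.0 and t["UB"] == 3.0
        assert t["ALK"] == 0.0 and t["RNG"] == 0.0

    def test_halogen_weighting(self, make_mol):
        t = topo.mlogp_terms(make_mol("FC(Cl)Br"))
        assert t["CX"] == pytest.approx(1 + 0.5 + 1.0 + 1.5)

    def test_methyl_never_decreases_cx(self, make_mol):
        for base, plus in [("CCO", "CC(C)O"), ("c1ccccc1", "Cc1ccccc1")]:
            assert (topo.mlogp_terms(make_mol(plus))["CX"]
                    >= topo.mlogp_terms(make_mol(base))["CX"])

    def test_reorder_invariant(self, make_mol):
        m = make_mol("CC(=O)Nc1ccc([N+](=O)[O-])cc1")
        assert topo.mlogp(m).value == pytest.approx(topo.mlogp(reorder(m)).value, abs=1e-12)

    def test_alkane_flag(self, make_mol):
        assert topo.mlogp_terms(make_mol("CCCCC"))["ALK"] == 1.0
        assert topo.mlogp_terms(make_mol("CCO"))["ALK"] == 0.0


class TestBLTF96:
    def test_equal_mlogp_gives_equal_bltf96(self, make_mol):
        a, b = make_mol("CCCC"), make_mol("CCCC")
        assert topo.bltf96(a).value == topo.bltf96(b).value

    def test_linear_in_mlogp(self, make_mol):
        a, b = make_mol("CCCC"), make_mol("CCCCCC")
        d_ml = topo.mlogp(b).value - topo.mlogp(a).value
        d_bl = topo.bltf96(b).value - topo.bltf96(a).value
        assert d_bl == pytest.approx(topo.BLTF96_SLOPE * d_ml, abs=1e-12)

    def test_slope_sign_matches_constants(self, make_mol):
        # higher logP -> lower baseline-toxicity LC50 (negative slope)
        assert topo.BLTF96_SLOPE < 0
        a, b = make_mol("CC"), make_mol("CCCCCCCC")
        assert topo.bltf96(b).value < topo.bltf96(a).value


class TestGVWIndex:
    def test_codomain(self, oracle_molecules):
        for mol in oracle_molecules:
            assert topo.gvw_druglike_index(mol).value in (0.0, 1.0)

    def test_huge_molecule_fails(self, make_mol):
        big = make_mol("C" * 60)  # MW far above any drug range
        assert topo.gvw_druglike_index(big).value == 0.0

    def test_matches_range_table_oracle(self, make_mol):
        ranges = topo.GVW_RANGES["depressant"][80]
        for smiles in ("CN(C)CCCN1c2ccccc2CCc2ccccc21",  # inside all ranges
                       "CCN(CC)CCNC(=O)c1ccc(OC)cc1", "O=C(OCC)c1ccccc1N", "CCO"):
            m = make_mol(smiles)
            molh = m.with_hs
            props = {"alogp": Crippen.MolLogP(molh), "mr": Crippen.MolMR(molh),
                     "mw": Descriptors.MolWt(molh), "natoms": molh.GetNumAtoms()}
            expect = float(all(lo <= props[k] <= hi for k, (lo, hi) in ranges.items()))
            assert topo.gvw_druglike_index(m).value == expect

    def test_both_outcomes_reachable(self, make_mol):
        assert topo.gvw_druglike_index(make_mol("CN(C)CCCN1c2ccccc2CCc2ccccc21")).value == 1.0
        assert topo.gvw_druglike_index(make_mol("CCO")).value == 0.0


class TestLipinskiProperties:
    def test_water(self, make_mol):
        p = topo.lipinski_properties(make_mol("O"))
        assert p.hbd == 1 and p.hba == 1
        assert p.mw == pytest.approx(18.02, abs=0.01)

    def test_methane(self, make_mol):
        p = topo.lipinski_properties(make_mol("C"))
        assert p.hbd == 0 and p.hba == 0

    def test_glycine_mw(self, make_mol):
        assert topo.lipinski_properties(make_mol("NCC(=O)O")).mw == pytest.approx(75.07, abs=0.01)

    def test_donor_counted_once_per_heteroatom(self, make_mol):
        # primary amine: one donor heteroatom despite two N-H bonds
        assert topo.lipinski_properties(make_mol("NC")).hbd == 1
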