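"""Molfile parsing, formulas, canonical keys, hydrogen topicity.

The brute-force oracle for hydrogen equivalence enumerates all colored-graph
automorphisms with networkx VF2 (independent of the package's own canonical
search) and applies the same parity-admissibility rule.
"""

import itertools
import random

import networkx as nx
import numpy as np
import pytest

import nmrkit as nk
from nmrkit.molecule import (
    MolfileError,
    canonical_key,
    check_answer,
    equivalent_hydrogens,
    molecular_formula,
    parse_molfile,
    renumber_atoms,
    write_molfile,
)

from conftest import make_molfile


class TestParseMolfile:
    def test_ethanol_atoms_bonds_implicit_h(self, ethanol):
        assert [a.element for a in ethanol.atoms] == ["C", "C", "O"]
        assert len(ethanol.bonds) == 2
        assert ethanol.implicit_h == [3, 2, 1]

    def test_benzene_implicit_h(self, benzene_kekule_a):
        assert benzene_kekule_a.implicit_h == [1] * 6

    def test_charged_nitrogen_valence(self):
        mol = parse_molfile(make_molfile(["N", "C"], [(0, 1, 1)], charges={0: 1}))
        assert mol.implicit_h[0] == 3  # ammonium-like N+

    def test_corrupt_counts_line_rejected(self):
        bad = nk.simulate.ETHANOL_MOLFILE.replace("  3  2", "  x  2")
        with pytest.raises(MolfileError, match="line 4"):
            parse_molfile(bad)

    def test_counts_promise_more_atoms_than_present(self):
        bad = make_molfile(["C", "C"], [(0, 1, 1)]).replace("  2  1", "  9  1")
        with pytest.raises(MolfileError):
            parse_molfile(bad)

    def test_v3000_rejected(self):
        bad = nk.simulate.ETHANOL_MOLFILE.replace("V2000", "V3000")
        with pytest.raises(MolfileError, match="V3000"):
            parse_molfile(bad)

    def test_write_parse_round_trip(self, butanol_r):
        again = parse_molfile(write_molfile(butanol_r))
        assert canonical_key(again) == canonical_key(butanol_r)


class TestMolecularFormula:
    @pytest.mark.parametrize("fixture,expected", [
        ("ethanol", "C2H6O"),
        ("benzene_kekule_a", "C6H6"),
        ("dimethoxybenzene", "C8H10O2"),
        ("butanol_r", "C4H10O"),
    ])
    def test_hill_order(self, fixture, expected, request):
        assert molecular_formula(request.getfixturevalue(fixture)) == expected

    def test_no_carbon_alphabetical(self):
        water = parse_molfile(make_molfile(["O"], []))
        assert molecular_formula(water) == "H2O"


# ---------------------------------------------------------------------------
# brute-force automorphism oracle

def _ring_normalized_orders(mol):
    """Alternating single/double even rings -> order 1.5 (oracle-side copy)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.a1, b.a2) for b in mol.bonds)
    orders = {frozenset((b.a1, b.a2)): float(b.order) for b in mol.bonds}
    for cycle in nx.cycle_basis(g):
        if len(cycle) % 2 or len(cycle) < 4:
            continue
        ring = [frozenset((cycle[k], cycle[(k + 1) % len(cycle)])) for k in range(len(cycle))]
        if any(e not in orders for e in ring):
            continue
        seq = [orders[e] for e in ring]
        if all(o in (1.0, 2.0) for o in seq) and all(
            seq[k] != seq[(k + 1) % len(seq)] for k in range(len(seq))
        ):
            for e in ring:
                orders[e] = 1.5
    return orders


def _explicit_graph(mol):
    g = nx.Graph()
    labels = {}
    for i, a in enumerate(mol.atoms):
        g.add_node(i)
        labels[i] = (a.element, a.charge, a.isotope)
    orders = _ring_normalized_orders(mol)
    for b in mol.bonds:
        g.add_edge(b.a1, b.a2, order=orders[frozenset((b.a1, b.a2))])
    nid = len(mol.atoms)
    h_of = {}
    for i in range(len(mol.atoms)):
        for _ in range(mol.implicit_h[i]):
            g.add_node(nid)
            labels[nid] = ("H", 0, 0)
            g.add_edge(i, nid, order=1)
            h_of[nid] = i
            nid += 1
    nx.set_node_attributes(g, labels, "label")
    return g, h_of


def _perm_sign(seq_a, seq_b):
    index = {v: k for k, v in enumerate(seq_b)}
    target = [index[v] for v in seq_a]
    sign = 1
    for i in range(len(target)):
        while target[i] != i:
            j = target[i]
            target[i], target[j] = target[j], target[i]
            sign = -sign
    return sign


def _oracle_classes(mol):
    """Hydrogen orbits from exhaustive VF2 automorphism enumeration."""
    g, h_of = _explicit_graph(mol)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    flagged = [i for i, a in enumerate(mol.atoms) if a.parity in (1, 2)]
    virtual = [
        i for i in range(len(mol.atoms))
        if mol.atoms[i].parity == 0 and g.degree(i) == 4
        and sum(1 for j in g.neighbors(i) if g.nodes[j]["label"][0] == "H") == 2
    ]
    parent = {h: h for h in h_of}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for iso in gm.isomorphisms_iter():
        verdicts = []
        ok = True
        for a in flagged:
            b = iso[a]
            if mol.atoms[b].parity not in (1, 2):
                ok = False
                break
            ref_a = sorted(g.neighbors(a))
            image = [iso[x] for x in ref_a]
            sign = _perm_sign(image, sorted(image))
            induced = mol.atoms[a].parity if sign > 0 else 3 - mol.atoms[a].parity
            verdicts.append(induced == mol.atoms[b].parity)
        if not ok:
            continue
        for c in virtual:
            if iso[c] != c:
                continue
            ref = sorted(g.neighbors(c))
            verdicts.append(_perm_sign([iso[x] for x in ref], ref) > 0)
        if verdicts and not (all(verdicts) or not any(verdicts)):
            continue
        for h in h_of:
            ra, rb = find(h), find(iso[h])
            if ra != rb:
                parent[ra] = rb
    groups = {}
    slot = {}
    counts = {}
    for h in sorted(h_of):
        heavy = h_of[h]
        slot[h] = counts.get(heavy, 0)
        counts[heavy] = slot[h] + 1
    for h in h_of:
        groups.setdefault(find(h), []).append((h_of[h], slot[h]))
    return sorted(sorted(c) for c in groups.values())


ALL_FIXTURES = ["ethanol", "benzene_kekule_a", "dimethoxybenzene", "butanol_r",
                "butanol_s", "dimethyl_ether"]


class TestEquivalentHydrogens:
    def test_benzene_single_class_of_six(self, benzene_kekule_a):
        eq = equivalent_hydrogens(benzene_kekule_a)
        assert len(eq.classes) == 1
        assert len(eq.classes[0]) == 6
        assert eq.topicity == ["homotopic_or_equivalent"]

    def test_ethanol_three_classes(self, ethanol):
        eq = equivalent_hydrogens(ethanol)
        assert sorted(len(c) for c in eq.classes) == [1, 2, 3]

    def test_dimethoxybenzene_ring_and_methyl_classes(self, dimethoxybenzene):
        eq = equivalent_hydrogens(dimethoxybenzene)
        assert sorted(len(c) for c in eq.classes) == [4, 6]

    def test_butanol_ch2_diastereotopic(self, butanol_r):
        eq = equivalent_hydrogens(butanol_r)
        dia = [c for c, t in zip(eq.classes, eq.topicity) if t == "diastereotopic"]
        assert len(dia) == 2
        assert all(len(c) == 1 and c[0][0] == 2 for c in dia)  # both on C3 (index 2)

    @pytest.mark.parametrize("fixture", ALL_FIXTURES)
    def test_matches_brute_force_oracle(self, fixture, request):
        mol = request.getfixturevalue(fixture)
        eq = equivalent_hydrogens(mol)
        assert sorted(sorted(c) for c in eq.classes) == _oracle_classes(mol)

    @pytest.mark.parametrize("fixture", ALL_FIXTURES)
    def test_partition_covers_all_hydrogens(self, fixture, request):
        mol = request.getfixturevalue(fixture)
        eq = equivalent_hydrogens(mol)
        formula = molecular_formula(mol)
        import re
        m = re.search(r"H(\d*)", formula)
        n_h = int(m.group(1) or 1) if m else 0
        assert eq.n_hydrogens == n_h
        flat = [p for c in eq.classes for p in c]
        assert len(flat) == len(set(flat))


class TestCanonicalKey:
    @pytest.mark.parametrize("fixture", ALL_FIXTURES)
    def test_invariant_under_100_random_renumberings(self, fixture, request):
        mol = request.getfixturevalue(fixture)
        key = canonical_key(mol)
        rng = random.Random(17)
        n = len(mol.atoms)
        for _ in range(100):
            perm = list(range(n))
            rng.shuffle(perm)
            assert canonical_key(renumber_atoms(mol, perm)) == key

    def test_kekule_forms_share_one_key(self, benzene_kekule_a, benzene_kekule_b):
        assert canonical_key(benzene_kekule_a) == canonical_key(benzene_kekule_b)

    def test_constitutional_isomers_differ(self, ethanol, dimethyl_ether):
        assert canonical_key(ethanol) != canonical_key(dimethyl_ether)

    def test_enantiomers_differ_with_stereo_only(self, butanol_r, butanol_s):
        assert canonical_key(butanol_r) != canonical_key(butanol_s)
        assert canonical_key(butanol_r, stereo=False) == canonical_key(butanol_s, stereo=False)

    def test_parity_flag_survives_renumbering(self, butanol_r):
        rng = random.Random(3)
        for _ in range(20):
            perm = list(range(5))
            rng.shuffle(perm)
            assert canonical_key(renumber_atoms(butanol_r, perm)) == canonical_key(butanol_r)

    def test_refinement_classes_never_split_true_orbits(self, dimethoxybenzene):
        # heavy-atom refinement colors vs exact orbits of the explicit graph
        from nmrkit.molecule import _ColoredGraph, _explicit_h_graph, _rank

        graph, h_nodes, _, _ = _explicit_h_graph(dimethoxybenzene)
        ranks = graph.refine(_rank([(c,) for c in graph.base_colors]))
        _, autos, _ = graph.canonical()
        for sigma in autos:
            for v in range(graph.n):
                assert ranks[v] == ranks[sigma[v]]


class TestCheckAnswer:
    def test_identical_structure_shuffled(self, ethanol):
        shuffled = renumber_atoms(ethanol, [2, 0, 1])
        assert check_answer(shuffled, ethanol) == "correct"

    def test_same_formula_different_skeleton(self, ethanol, dimethyl_ether):
        assert check_answer(dimethyl_ether, ethanol) == "wrong_constitution"

    def test_opposite_parity(self, butanol_r, butanol_s):
        assert check_answer(butanol_r, butanol_s, stereo=True) == "wrong_stereo"
        assert check_answer(butanol_r, butanol_s, stereo=False) == "correct"


class TestRDKitCrossCheck:
    """Constitutional verdicts cross-checked against RDKit canonical SMILES."""

    def _rdkit_canonical(self, mol):
        from rdkit import Chem

        rd = Chem.MolFromMolBlock(write_molfile(mol), sanitize=True)
        assert rd is not None
        return Chem.MolToSmiles(rd)

    @pytest.mark.parametrize("a,b,same", [
        ("ethanol", "dimethyl_ether", False),
        ("benzene_kekule_a", "benzene_kekule_b", True),
        ("butanol_r", "butanol_s", True),  # constitution only
    ])
    def test_agreement_on_pairs(self, a, b, same, request):
        ma, mb = request.getfixturevalue(a), request.getfixturevalue(b)
        ours = canonical_key(ma, stereo=False) == canonical_key(mb, stereo=False)
        theirs = self._rdkit_canonical(ma) == self._rdkit_canonical(mb)
        assert ours == theirs == same

    def test_renumbering_agreement(self, dimethoxybenzene):
        shuffled = renumber_atoms(dimethoxybenzene, list(np.random.default_rng(1).permutation(10)))
        assert self._rdkit_canonical(shuffled) == self._rdkit_canonical(dimethoxybenzene)
        assert canonical_key(shuffled) == canonical_key(dimethoxybenzene)
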