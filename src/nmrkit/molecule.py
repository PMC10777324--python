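"""Structure handling for assignment and answer checking.

MDL molfile (V2000) parsing, Hill-order molecular formulas, canonical keys
invariant under atom renumbering (with optional tetrahedral parity), and
hydrogen equivalence classes including recognition of diastereotopic CH2
protons.

Equivalence is computed from graph-automorphism orbits: iterative
neighborhood-label (Morgan/Weisfeiler-Lehman style) refinement followed by a
canonical-form permutation search whose minimal leaves enumerate the full
automorphism group exactly on small graphs.  Stereochemistry enters through
molfile tetrahedral parity flags: an automorphism is admitted when it either
preserves every flagged centre's configuration or inverts all of them (a
mirror image — enantiotopic hydrogens are NMR-equivalent).  A CH2 whose two
hydrogens are exchanged only by configuration-breaking automorphisms is split
into two classes labelled diastereotopic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "EquivalenceClasses",
    "MolfileError",
    "parse_molfile",
    "write_molfile",
    "renumber_atoms",
    "molecular_formula",
    "equivalent_hydrogens",
    "canonical_key",
    "check_answer",
]

MAX_EXACT_HEAVY_ATOMS = 64


class MolfileError(ValueError):
    pass


@dataclass
class Atom:
    element: str
    charge: int = 0
    isotope: int = 0
    parity: int = 0  # 0 none, 1 odd, 2 even (molfile convention)


@dataclass
class Bond:
    a1: int  # 0-based
    a2: int
    order: int = 1
    stereo: int = 0


@dataclass
class Molecule:
    atoms: list[Atom]
    bonds: list[Bond]
    implicit_h: list[int] = field(default_factory=list)
    source_molfile: str = ""

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a1 == i:
                out.append(b.a2)
            elif b.a2 == i:
                out.append(b.a1)
        return out

    def bond_order_sum(self, i: int) -> int:
        return sum(b.order for b in self.bonds if i in (b.a1, b.a2))


@dataclass
class EquivalenceClasses:
    """Partition of all hydrogen positions into equivalence classes.

    A position is ``(heavy_atom_index, slot)``; slots number the hydrogens on
    one heavy atom.  ``topicity[k]`` labels class ``k`` as
    ``"homotopic_or_equivalent"`` or ``"diastereotopic"``.
    """

    classes: list[list[tuple[int, int]]]
    topicity: list[str]
    approximate: bool = False

    @property
    def n_hydrogens(self) -> int:
        return sum(len(c) for c in self.classes)


# ---------------------------------------------------------------------------
# molfile I/O

_BASE_VALENCE = {
    "C": (4,), "N": (3,), "O": (2,), "F": (1,), "Cl": (1,), "Br": (1,),
    "I": (1,), "H": (1,), "B": (3,), "Si": (4,), "P": (3, 5), "S": (2, 4, 6),
}

_CHARGE_CODE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


def parse_molfile(text: str) -> Molecule:
    """Parse a V2000 molfile; implicit hydrogens follow standard valence rules."""
    lines = text.replace("\r\n", "\n").split("\n")
    if len(lines) < 4:
        raise MolfileError("molfile too short: no counts line (line 4)")
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileError("V3000 molfiles are not supported (V2000 only)")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise MolfileError(f"corrupt counts line (line 4): {counts!r}") from exc

    atoms: list[Atom] = []
    for k in range(n_atoms):
        lineno = 5 + k
        if 4 + k >= len(lines):
            raise MolfileError(f"counts line promises {n_atoms} atoms but file ends at line {lineno - 1}")
        line = lines[4 + k]
        element = line[31:34].strip() if len(line) >= 34 else ""
        try:
            if element and element[0].isalpha():
                charge_code = int(line[36:39]) if len(line) >= 39 and line[36:39].strip() else 0
                parity = int(line[39:42]) if len(line) >= 42 and line[39:42].strip() else 0
            else:  # whitespace-separated fallback for non-column-aligned files
                parts = line.split()
                element = parts[3]
                charge_code = int(parts[5]) if len(parts) > 5 else 0
                parity = int(parts[6]) if len(parts) > 6 else 0
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"malformed atom line {lineno}: {line!r}") from exc
        if not element or not element[0].isalpha():
            raise MolfileError(f"malformed atom line {lineno}: {line!r}")
        atoms.append(Atom(element=element, charge=_CHARGE_CODE.get(charge_code, 0),
                          parity=parity if parity in (1, 2) else 0))

    bonds: list[Bond] = []
    for k in range(n_bonds):
        lineno = 5 + n_atoms + k
        if 4 + n_atoms + k >= len(lines):
            raise MolfileError(f"counts line promises {n_bonds} bonds but file ends at line {lineno - 1}")
        line = lines[4 + n_atoms + k]
        try:
            if len(line) >= 9:
                a1 = int(line[0:3]); a2 = int(line[3:6]); order = int(line[6:9])
                stereo = int(line[9:12]) if len(line) >= 12 and line[9:12].strip() else 0
            else:
                parts = line.split()
                a1, a2, order = int(parts[0]), int(parts[1]), int(parts[2])
                stereo = int(parts[3]) if len(parts) > 3 else 0
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"malformed bond line {lineno}: {line!r}") from exc
        if not (1 <= a1 <= n_atoms and 1 <= a2 <= n_atoms):
            raise MolfileError(f"bond line {lineno} references atom out of range: {line!r}")
        bonds.append(Bond(a1 - 1, a2 - 1, order, stereo))

    for line in lines[4 + n_atoms + n_bonds:]:
        if line.startswith("M  CHG"):
            parts = line.split()
            n = int(parts[2])
            for i in range(n):
                atoms[int(parts[3 + 2 * i]) - 1].charge = int(parts[4 + 2 * i])
        elif line.startswith("M  ISO"):
            parts = line.split()
            n = int(parts[2])
            for i in range(n):
                atoms[int(parts[3 + 2 * i]) - 1].isotope = int(parts[4 + 2 * i])
        elif line.startswith("M  END"):
            break

    mol = Molecule(atoms=atoms, bonds=bonds, source_molfile=text)
    mol.implicit_h = [_implicit_h(mol, i) for i in range(n_atoms)]
    return mol


def _implicit_h(mol: Molecule, i: int) -> int:
    atom = mol.atoms[i]
    if atom.element not in _BASE_VALENCE:
        return 0
    used = mol.bond_order_sum(i)
    options = _BASE_VALENCE[atom.element]
    if atom.element in ("N", "P", "O", "S"):
        options = tuple(v + atom.charge for v in options)
    elif atom.element in ("C", "B"):
        options = tuple(v - abs(atom.charge) for v in options)
    for v in sorted(options):
        if used <= v:
            return v - used
    return 0


def write_molfile(mol: Molecule, title: str = "") -> str:
    lines = [title, "  nmrkit", ""]
    lines.append(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    charged = []
    isotopes = []
    for i, a in enumerate(mol.atoms):
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {a.element:<3}"
            f" 0  0{a.parity:3d}  0  0  0  0  0  0  0  0  0"
        )
        if a.charge:
            charged.append((i + 1, a.charge))
        if a.isotope:
            isotopes.append((i + 1, a.isotope))
    for b in mol.bonds:
        lines.append(f"{b.a1 + 1:3d}{b.a2 + 1:3d}{b.order:3d}{b.stereo:3d}")
    for i, chg in charged:
        lines.append(f"M  CHG  1 {i:3d} {chg:3d}")
    for i, iso in isotopes:
        lines.append(f"M  ISO  1 {i:3d} {iso:3d}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def renumber_atoms(mol: Molecule, perm: list[int]) -> Molecule:
    """Return the molecule with atom ``i`` moved to index ``perm[i]``.

    Tetrahedral parity flags are adjusted for the change of neighbor index
    order (an odd permutation of a centre's neighbor list flips its parity).
    """
    n = len(mol.atoms)
    inv = [0] * n
    for old, new in enumerate(perm):
        inv[new] = old
    atoms = []
    for new in range(n):
        old = inv[new]
        a = mol.atoms[old]
        parity = a.parity
        if parity:
            old_ref = sorted(mol.neighbors(old))
            new_ref = sorted(perm[x] for x in old_ref)
            image = [perm[x] for x in old_ref]
            if _perm_sign_between(image, new_ref) < 0:
                parity = 3 - parity
        atoms.append(Atom(a.element, a.charge, a.isotope, parity))
    bonds = [Bond(perm[b.a1], perm[b.a2], b.order, b.stereo) for b in mol.bonds]
    out = Molecule(atoms=atoms, bonds=bonds)
    out.implicit_h = [mol.implicit_h[inv[new]] for new in range(n)]
    out.source_molfile = write_molfile(out)
    return out


def _perm_sign_between(seq_a: list[int], seq_b: list[int]) -> int:
    """Sign of the permutation carrying ``seq_a`` onto ``seq_b`` (same items)."""
    index = {v: k for k, v in enumerate(seq_b)}
    target = [index[v] for v in seq_a]
    sign = 1
    target = list(target)
    for i in range(len(target)):
        while target[i] != i:
            j = target[i]
            target[i], target[j] = target[j], target[i]
            sign = -sign
    return sign


# ---------------------------------------------------------------------------
# formula

def molecular_formula(mol: Molecule) -> str:
    """Hill-order molecular formula including implicit hydrogens."""
    counts: Counter[str] = Counter()
    for i, a in enumerate(mol.atoms):
        counts[a.element] += 1
        counts["H"] += mol.implicit_h[i]
    parts = []
    if counts.get("C"):
        order = ["C"] + (["H"] if counts.get("H") else []) + sorted(
            e for e in counts if e not in ("C", "H") and counts[e]
        )
    else:
        order = sorted(e for e in counts if counts[e])
    for e in order:
        n = counts[e]
        parts.append(e + (str(n) if n > 1 else ""))
    return "".join(parts)


# ---------------------------------------------------------------------------
# colored-graph canonicalization

def _normalized_bond_labels(mol: Molecule) -> dict[tuple[int, int], float]:
    """Bond-order edge labels with alternating single/double rings set to 1.5.

    Keeps the two Kekulé forms of an aromatic ring canonical-equal without
    full aromaticity perception.
    """
    import networkx as nx

    labels = {}
    for b in mol.bonds:
        labels[frozenset((b.a1, b.a2))] = float(b.order)
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.a1, b.a2) for b in mol.bonds)
    for cycle in nx.cycle_basis(g):
        if len(cycle) % 2 or len(cycle) < 4:
            continue
        orders = []
        ok = True
        for k in range(len(cycle)):
            e = frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
            if e not in labels:
                ok = False
                break
            orders.append(labels[e])
        if not ok:
            continue
        if all(o in (1.0, 2.0) for o in orders) and all(
            orders[k] != orders[(k + 1) % len(orders)] for k in range(len(orders))
        ):
            for k in range(len(cycle)):
                labels[frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))] = 1.5
    return {tuple(sorted(e)): v for e, v in labels.items()}


class _ColoredGraph:
    """Small colored graph with labelled edges, for canonical search."""

    def __init__(self, n: int, base_colors: list, edges: dict[tuple[int, int], float]):
        self.n = n
        self.base_colors = base_colors
        self.edges = edges
        self.adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for (i, j), lab in edges.items():
            self.adj[i].append((j, lab))
            self.adj[j].append((i, lab))

    def refine(self, colors: list) -> list[int]:
        """Stable neighborhood refinement; returns integer color ranks."""
        current = [(c,) for c in colors]
        ranks = _rank(current)
        while True:
            sigs = [
                (ranks[i], tuple(sorted((lab, ranks[j]) for j, lab in self.adj[i])))
                for i in range(self.n)
            ]
            new_ranks = _rank(sigs)
            if new_ranks == ranks:
                return ranks
            ranks = new_ranks

    def canonical(self, max_leaves: int = 50000):
        """Minimal-certificate search.

        Returns ``(order, automorphisms, complete)`` where ``order`` maps
        canonical position -> vertex, ``automorphisms`` is the list of vertex
        permutations (as tuples) enumerated from the minimal leaves, and
        ``complete`` is False when the leaf cap was hit.
        """
        best: dict = {"cert": None, "orders": []}
        state = {"leaves": 0, "complete": True}

        def certificate(order: list[int]):
            pos = [0] * self.n
            for p, v in enumerate(order):
                pos[v] = p
            nodes = tuple(self.base_colors[v] for v in order)
            edges = tuple(sorted(
                (min(pos[i], pos[j]), max(pos[i], pos[j]), lab)
                for (i, j), lab in self.edges.items()
            ))
            return (nodes, edges)

        def rec(ranks: list[int]):
            if state["leaves"] >= max_leaves:
                state["complete"] = False
                return
            cells: dict[int, list[int]] = {}
            for v, r in enumerate(ranks):
                cells.setdefault(r, []).append(v)
            target = None
            for r in sorted(cells):
                if len(cells[r]) > 1:
                    target = cells[r]
                    break
            if target is None:
                order = sorted(range(self.n), key=lambda v: ranks[v])
                cert = certificate(order)
                state["leaves"] += 1
                if best["cert"] is None or cert < best["cert"]:
                    best["cert"] = cert
                    best["orders"] = [order]
                elif cert == best["cert"]:
                    best["orders"].append(order)
                return
            for v in target:
                sigs = [(ranks[u], 0 if u == v else 1) for u in range(self.n)]
                rec(self.refine(_rank(sigs)))

        rec(self.refine(_rank([(c,) for c in self.base_colors])))
        orders = best["orders"]
        ref = orders[0]
        autos = []
        seen = set()
        for o in orders:
            # sigma maps ref labelling onto o labelling: vertex ref[p] -> o[p]
            sigma = tuple(dict(zip(ref, o))[v] for v in range(self.n))
            if sigma not in seen:
                seen.add(sigma)
                autos.append(sigma)
        return ref, autos, state["complete"]


def _inverse_positions(order: list[int]) -> list[int]:
    pos = [0] * len(order)
    for p, v in enumerate(order):
        pos[v] = p
    return pos


def _rank(signatures: list) -> list[int]:
    ordered = sorted(set(signatures))
    index = {s: k for k, s in enumerate(ordered)}
    return [index[s] for s in signatures]


# ---------------------------------------------------------------------------
# canonical key

def canonical_key(mol: Molecule, stereo: bool = True) -> str:
    """Canonical text key, invariant under atom renumbering.

    Encodes element, charge, isotope, hydrogen counts and (normalized) bond
    orders; with ``stereo=True`` tetrahedral parity flags are appended as a
    renumbering-invariant descriptor.
    """
    n = len(mol.atoms)
    if n == 0:
        return "empty"
    labels = _normalized_bond_labels(mol)
    base = [
        (mol.atoms[i].element, mol.atoms[i].charge, mol.atoms[i].isotope,
         mol.implicit_h[i] + sum(1 for j in mol.neighbors(i) if mol.atoms[j].element == "H"))
        for i in range(n)
    ]
    graph = _ColoredGraph(n, base, labels)
    order, autos, _complete = graph.canonical()
    pos = _inverse_positions(order)
    node_str = ".".join(
        f"{e}{'+' if c > 0 else ''}{c if c else ''}{'i' + str(iso) if iso else ''}H{h}"
        for e, c, iso, h in (base[v] for v in order)
    )
    edge_str = ",".join(
        f"{a}-{b}:{lab:g}"
        for a, b, lab in sorted(
            (min(pos[i], pos[j]), max(pos[i], pos[j]), lab)
            for (i, j), lab in labels.items()
        )
    )
    key = f"{node_str}|{edge_str}"
    if stereo:
        stereo_strs = []
        for o in ([order] + [[sigma[v] for v in order] for sigma in autos]):
            stereo_strs.append(_stereo_descriptor(mol, o))
        key += "|" + min(stereo_strs)
    return key


def _stereo_descriptor(mol: Molecule, order: list[int]) -> str:
    """Parity flags re-expressed against canonical neighbor ordering."""
    pos = _inverse_positions(order)
    entries = []
    for i, a in enumerate(mol.atoms):
        if a.parity not in (1, 2):
            continue
        ref = sorted(mol.neighbors(i))  # molfile convention: index order, implicit H last
        canon = sorted(ref, key=lambda x: pos[x])
        parity = a.parity
        if _perm_sign_between(ref, canon) < 0:
            parity = 3 - parity
        entries.append((pos[i], parity))
    return ";".join(f"{p}:{par}" for p, par in sorted(entries))


def check_answer(candidate: Molecule, solution: Molecule, stereo: bool = True) -> str:
    """Compare two structures: ``correct`` / ``wrong_constitution`` / ``wrong_stereo``."""
    if canonical_key(candidate, stereo=False) != canonical_key(solution, stereo=False):
        return "wrong_constitution"
    if stereo and canonical_key(candidate, stereo=True) != canonical_key(solution, stereo=True):
        return "wrong_stereo"
    return "correct"


# ---------------------------------------------------------------------------
# hydrogen equivalence / topicity

def _explicit_h_graph(mol: Molecule):
    """Graph with implicit hydrogens materialized as explicit leaf nodes.

    Returns ``(graph, h_nodes, h_positions, heavy_of_h)`` where ``h_nodes``
    lists every hydrogen node id and ``h_positions`` maps node id to a
    ``(heavy_index, slot)`` position.
    """
    n = len(mol.atoms)
    base = [(a.element, a.charge, a.isotope) for a in mol.atoms]
    edges = {}
    labels = _normalized_bond_labels(mol)
    edges.update(labels)
    h_nodes: list[int] = []
    h_positions: dict[int, tuple[int, int]] = {}
    heavy_of_h: dict[int, int] = {}
    slot_count = [0] * n
    for i, a in enumerate(mol.atoms):
        if a.element == "H":
            nb = mol.neighbors(i)
            heavy = nb[0] if nb else i
            h_nodes.append(i)
            h_positions[i] = (heavy, slot_count[heavy])
            heavy_of_h[i] = heavy
            slot_count[heavy] += 1
    next_id = n
    for i in range(n):
        for _ in range(mol.implicit_h[i]):
            base.append(("H", 0, 0))
            edges[(i, next_id)] = 1.0
            h_nodes.append(next_id)
            h_positions[next_id] = (i, slot_count[i])
            heavy_of_h[next_id] = i
            slot_count[i] += 1
            next_id += 1
    graph = _ColoredGraph(len(base), base, edges)
    return graph, h_nodes, h_positions, heavy_of_h


def _stereo_consistency(mol: Molecule, graph: _ColoredGraph, sigma,
                        virtual_centres: list[int]) -> bool:
    """Is ``sigma`` a configuration-respecting automorphism?

    Admitted when every flagged (and self-mapped virtual) centre is preserved,
    or every one is inverted (mirror image).
    """
    verdicts = []
    adj = {i: sorted(j for j, _ in graph.adj[i]) for i in range(graph.n)}
    flagged = [i for i, a in enumerate(mol.atoms) if a.parity in (1, 2)]
    for a in flagged:
        b = sigma[a]
        pb = mol.atoms[b].parity if b < len(mol.atoms) else 0
        if pb not in (1, 2):
            return False
        ref_a = adj[a]
        image = [sigma[x] for x in ref_a]
        ref_b = adj[b]
        if sorted(image) != ref_b:
            return False
        sign = _perm_sign_between(image, sorted(image))
        induced = mol.atoms[a].parity if sign > 0 else 3 - mol.atoms[a].parity
        verdicts.append(induced == pb)
    for c in virtual_centres:
        if sigma[c] != c:
            continue
        ref = adj[c]
        image = [sigma[x] for x in ref]
        sign = _perm_sign_between(image, ref)
        verdicts.append(sign > 0)
    if not verdicts:
        return True
    return all(verdicts) or not any(verdicts)


def equivalent_hydrogens(mol: Molecule) -> EquivalenceClasses:
    """Partition all hydrogens (implicit and explicit) into topicity classes.

    Exact automorphism orbits for molecules up to 64 heavy atoms; larger
    molecules fall back to a refinement-only partition flagged approximate.
    """
    graph, h_nodes, h_positions, heavy_of_h = _explicit_h_graph(mol)
    n_heavy = len(mol.atoms)
    if not h_nodes:
        return EquivalenceClasses(classes=[], topicity=[])

    if n_heavy > MAX_EXACT_HEAVY_ATOMS:
        ranks = graph.refine(_rank([(c,) for c in graph.base_colors]))
        groups: dict[int, list[int]] = {}
        for h in h_nodes:
            groups.setdefault(ranks[h], []).append(h)
        classes = [sorted(h_positions[h] for h in g) for g in groups.values()]
        classes.sort()
        return EquivalenceClasses(classes=classes,
                                  topicity=["homotopic_or_equivalent"] * len(classes),
                                  approximate=True)

    _order, autos, complete = graph.canonical()
    virtual = [
        i for i in range(n_heavy)
        if mol.atoms[i].parity == 0
        and len(graph.adj[i]) == 4
        and sum(1 for j, _ in graph.adj[i] if graph.base_colors[j][0] == "H") == 2
    ]
    valid = [s for s in autos if _stereo_consistency(mol, graph, s, virtual)]

    parent = {h: h for h in h_nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for sigma in valid:
        for h in h_nodes:
            if sigma[h] in parent:
                union(h, sigma[h])
    groups: dict[int, list[int]] = {}
    for h in h_nodes:
        groups.setdefault(find(h), []).append(h)
    classes = [sorted(h_positions[h] for h in g) for g in groups.values()]
    classes.sort()

    class_of: dict[tuple[int, int], int] = {}
    for k, cls in enumerate(classes):
        for posn in cls:
            class_of[posn] = k
    topicity = ["homotopic_or_equivalent"] * len(classes)
    per_heavy: dict[int, list[tuple[int, int]]] = {}
    for posn in class_of:
        per_heavy.setdefault(posn[0], []).append(posn)
    for heavy, posns in per_heavy.items():
        if len(posns) == 2:
            k1, k2 = class_of[posns[0]], class_of[posns[1]]
            if k1 != k2:
                topicity[k1] = topicity[k2] = "diastereotopic"
    return EquivalenceClasses(classes=classes, topicity=topicity,
                              approximate=not complete)
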