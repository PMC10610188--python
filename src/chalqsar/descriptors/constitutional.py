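"""Count-based constitutional descriptors and druglikeness properties."""

from __future__ import annotations

from ..chem import Molecule, average_mw, molecular_formula
from .vector import DescriptorVector, _ELEMENTS_COUNTED


def _ring_bond_flags(mol: Molecule) -> list[bool]:
    """True for bonds that lie in a ring (non-bridge edges)."""
    adj = [[] for _ in mol.atoms]
    for bi, b in enumerate(mol.bonds):
        adj[b.i].append((b.j, bi))
        adj[b.j].append((b.i, bi))
    n = len(mol.atoms)
    disc = [-1] * n
    low = [0] * n
    flags = [True] * len(mol.bonds)
    timer = 0

    # iterative Tarjan bridge finding
    for root in range(n):
        if disc[root] != -1:
            continue
        stack = [(root, -1, iter(adj[root]))]
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            v, parent_edge, it = stack[-1]
            advanced = False
            for w, bi in it:
                if bi == parent_edge:
                    continue
                if disc[w] == -1:
                    disc[w] = low[w] = timer
                    timer += 1
                    stack.append((w, bi, iter(adj[w])))
                    advanced = True
                    break
                low[v] = min(low[v], disc[w])
            if advanced:
                continue
            stack.pop()
            if stack:
                u = stack[-1][0]
                low[u] = min(low[u], low[v])
                if low[v] > disc[u]:
                    flags[parent_edge] = False  # bridge: not in a ring
    return flags


def rotatable_bond_count(mol: Molecule) -> int:
    """Veber-style rotatable bonds: acyclic single bonds between two
    non-terminal heavy atoms, excluding C-N amide bonds."""
    in_ring = _ring_bond_flags(mol)
    adj = mol.adjacency()

    def heavy_degree(i: int) -> int:
        return sum(1 for j, _ in adj[i] if mol.atoms[j].element != "H")

    def is_amide_cn(i: int, j: int) -> bool:
        for a, b in ((i, j), (j, i)):
            if mol.atoms[a].element == "C" and mol.atoms[b].element == "N":
                if any(
                    order == 2 and mol.atoms[k].element == "O" for k, order in adj[a]
                ):
                    return True
        return False

    count = 0
    for bi, b in enumerate(mol.bonds):
        if b.order != 1 or in_ring[bi]:
            continue
        ai, aj = mol.atoms[b.i], mol.atoms[b.j]
        if ai.element == "H" or aj.element == "H":
            continue
        if heavy_degree(b.i) < 2 or heavy_degree(b.j) < 2:
            continue  # terminal bond
        if is_amide_cn(b.i, b.j):
            continue
        count += 1
    return count


def constitutional_descriptors(mol: Molecule) -> DescriptorVector:
    """Element counts, relative counts (RNSA for sulfur), MW, Fsp3, RB,
    HBA/HBD and aromatic fraction.  Hydrogens must be explicit; relative
    counts use the all-atom total including hydrogens."""
    if not mol.hydrogens_explicit:
        raise ValueError("hydrogens must be explicit")
    vec = DescriptorVector()
    n_total = len(mol.atoms)
    counts = {e: 0 for e in _ELEMENTS_COUNTED}
    for a in mol.atoms:
        if a.element in counts:
            counts[a.element] += 1
    for e in _ELEMENTS_COUNTED:
        vec.set(f"n_{e}", float(counts[e]))
        vec.set(f"rel_n_{e}", counts[e] / n_total)
    vec.set("RNSA", counts["S"] / n_total)
    vec.set("n_atoms", float(n_total))
    heavy = mol.heavy_indices()
    vec.set("n_heavy", float(len(heavy)))
    vec.set("MW", average_mw(molecular_formula(mol)))

    adj = mol.adjacency()
    n_carbon = counts["C"]
    n_sp3 = 0
    for i in heavy:
        a = mol.atoms[i]
        if a.element != "C":
            continue
        if not a.is_aromatic and all(order == 1 for _, order in adj[i]):
            n_sp3 += 1
    vec.set("Fsp3", n_sp3 / n_carbon if n_carbon else 0.0)
    vec.set("RB", float(rotatable_bond_count(mol)))
    vec.set("HBA", float(counts["N"] + counts["O"]))
    n_hbd = sum(
        1
        for b in mol.bonds
        if {mol.atoms[b.i].element, mol.atoms[b.j].element} in ({"O", "H"}, {"N", "H"})
    )
    vec.set("HBD", float(n_hbd))
    n_aromatic = sum(1 for i in heavy if mol.atoms[i].is_aromatic)
    vec.set("Far", n_aromatic / len(heavy) if heavy else 0.0)
    return vec
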