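"""Neighborhood-symmetry atom classes and information-content indices.

Atoms are partitioned into equivalence classes by iterated neighborhood
refinement: order 0 is element identity, order k refines order k-1 by the
sorted multiset of (bond order, neighbor class) pairs.  IC_k is the Shannon
entropy of the class-size distribution; BIC_k divides it by log2 of the
bond count weighted by bond orders (aromatic = 1.5).  ABIC2 is BIC_2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from ..chem import Molecule
from .vector import MISSING


@dataclass
class AtomClassing:
    order: int
    class_id: list[int]

    def n_classes(self) -> int:
        return len(set(self.class_id))

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for c in self.class_id:
            counts[c] = counts.get(c, 0) + 1
        return sorted(counts.values())


def atom_classes(mol: Molecule, k: int) -> AtomClassing:
    """Order-k neighborhood equivalence classes with deterministic labels."""
    if k < 0:
        raise ValueError("order must be >= 0")
    adj = mol.adjacency()
    # order 0: element identity
    signatures: list = [a.element for a in mol.atoms]
    labels = _relabel(signatures)
    for _ in range(k):
        signatures = [
            (
                labels[i],
                tuple(sorted((order, labels[j]) for j, order in adj[i])),
            )
            for i in range(len(mol.atoms))
        ]
        labels = _relabel(signatures)
    return AtomClassing(order=k, class_id=labels)


def _relabel(signatures: list) -> list[int]:
    mapping = {sig: idx for idx, sig in enumerate(sorted(set(signatures)))}
    return [mapping[sig] for sig in signatures]


def information_content(
    mol: Molecule, k: int, normalizer: str = "bonds"
) -> tuple[float, Optional[float]]:
    """Return (IC_k in bits, BIC_k).

    ``normalizer="bonds"`` (default) divides by log2(q) where q is the sum of
    bond orders; ``"atoms"`` divides by log2(n) instead (alternative
    "average" convention).  BIC is MISSING when the normalizer is undefined
    (q <= 1, or n <= 1).
    """
    classing = atom_classes(mol, k)
    n = len(mol.atoms)
    ic = 0.0
    for size in classing.sizes():
        p = size / n
        ic -= p * math.log2(p)
    if normalizer == "bonds":
        q = mol.bond_order_total()
        denom = math.log2(q) if q > 1 else 0.0
    elif normalizer == "atoms":
        denom = math.log2(n) if n > 1 else 0.0
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    bic = ic / denom if denom > 0 else MISSING
    return ic, bic
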