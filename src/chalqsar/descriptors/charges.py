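"""Partial atomic charges by iterative partial equalization of orbital
electronegativity (PEOE), with the published 1980 parameter set.

Electronegativity is a quadratic in the atomic charge, chi(Q) = a + b*Q +
c*Q^2, parameterized per element and hybridization.  Charge flows along each
bond from the less to the more electronegative atom, scaled by the cation
electronegativity of the donor and damped by 0.5 per iteration.  Six
iterations, synchronous updates within an iteration: fully deterministic and
symmetric under atom reindexing.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..chem import ChemError, Molecule
from .vector import MISSING, DescriptorVector


class ChargeModelError(ChemError):
    pass


# (a, b, c) of chi(Q) = a + b*Q + c*Q^2, in eV; keys (element, hybridization)
_PEOE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", "s"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("S", "sp2"): (10.14, 9.13, 1.38),
}

# Cation electronegativity of hydrogen (special-cased in the original scheme).
_H_CATION_CHI = 20.02

_ITERATIONS = 6
_DAMPING = 0.5


@dataclass
class ChargeSet:
    values: list[float]
    model_tag: str = "peoe-1980"

    def total(self) -> float:
        return sum(self.values)


def _hybridization(mol: Molecule, i: int) -> str:
    atom = mol.atoms[i]
    if atom.element in ("H", "F", "Cl", "Br"):
        return "s" if atom.element == "H" else "sp3"
    orders = [order for _, order in mol.neighbors(i)]
    if atom.is_aromatic or 1.5 in orders:
        return "sp2"
    n_double = sum(1 for o in orders if o == 2)
    if any(o == 3 for o in orders) or n_double >= 2:
        return "sp"
    if n_double == 1:
        return "sp2"
    return "sp3"


def partial_charges(mol: Molecule) -> ChargeSet:
    """PEOE partial charges (e) for a hydrogen-explicit molecule."""
    if not mol.hydrogens_explicit:
        raise ChemError("hydrogens must be explicit for charge computation")
    params = []
    for i, atom in enumerate(mol.atoms):
        hyb = _hybridization(mol, i)
        key = (atom.element, hyb)
        if key not in _PEOE_PARAMS:
            # fall back to sp3 parameters of the element if defined
            key = (atom.element, "sp3")
        if key not in _PEOE_PARAMS:
            raise ChargeModelError(
                f"no PEOE parameters for element {atom.element!r} ({hyb})"
            )
        params.append(_PEOE_PARAMS[key])

    def chi(k: int, q: float) -> float:
        a, b, c = params[k]
        return a + b * q + c * q * q

    def chi_cation(k: int) -> float:
        if mol.atoms[k].element == "H":
            return _H_CATION_CHI
        a, b, c = params[k]
        return a + b + c

    charges = [float(a.formal_charge) for a in mol.atoms]
    for it in range(1, _ITERATIONS + 1):
        damp = _DAMPING**it
        delta = [0.0] * len(charges)
        for b in mol.bonds:
            chi_i = chi(b.i, charges[b.i])
            chi_j = chi(b.j, charges[b.j])
            if chi_i == chi_j:
                continue
            if chi_i < chi_j:
                donor, acceptor = b.i, b.j
            else:
                donor, acceptor = b.j, b.i
            dq = abs(chi_j - chi_i) / chi_cation(donor) * damp
            delta[donor] += dq
            delta[acceptor] -= dq
        charges = [q + d for q, d in zip(charges, delta)]
    return ChargeSet(values=charges)


def electrostatic_descriptors(mol: Molecule, charges: ChargeSet) -> DescriptorVector:
    """MPCO (minimal partial charge on an oxygen atom, MISSING without
    oxygen), the maximal positive charge, and the minimal charge overall."""
    if len(charges.values) != len(mol.atoms):
        raise ValueError("charge set does not match molecule")
    vec = DescriptorVector()
    oxy = [q for a, q in zip(mol.atoms, charges.values) if a.element == "O"]
    vec.set("MPCO", min(oxy) if oxy else MISSING)
    positives = [q for q in charges.values if q > 0]
    vec.set("max_pos_charge", max(positives) if positives else 0.0)
    vec.set("min_charge", min(charges.values))
    return vec
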