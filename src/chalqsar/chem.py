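"""Molecular data model, structure I/O, and formula/mass arithmetic.

The molecule model is a hydrogen-explicit atom/bond graph with optional 3D
coordinates.  Aromaticity is taken from the input notation (lowercase SMILES
atoms, V2000 bond type 4) and never perceived; aromatic bonds carry order 1.5.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Formula",
    "ChemError",
    "SmilesError",
    "MolfileError",
    "ElementError",
    "ValenceError",
    "parse_smiles",
    "read_molfile",
    "read_smiles_file",
    "add_hydrogens",
    "molecular_formula",
    "parse_formula",
    "average_mw",
    "monoisotopic_mz",
    "SUPPORTED_ELEMENTS",
    "ATOMIC_WEIGHT",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "VDW_RADIUS",
]

SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "S", "F", "Cl", "Br", "P", "K"}

# Older IUPAC standard atomic weights; chosen so that 2-decimal rounding
# reproduces published molecular weights (e.g. 286.78 for C16H11ClOS).
ATOMIC_WEIGHT = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984,
    "S": 32.065,
    "Cl": 35.453,
    "Br": 79.904,
    "P": 30.973762,
    "K": 39.0983,
}

# Most-abundant-isotope masses (u).
MONOISOTOPIC_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "Br": 78.9183376,
    "P": 30.97376151,
    "K": 38.9637065,
}

ELECTRON_MASS = 0.00054858

# Bondi van der Waals radii (Angstrom).
VDW_RADIUS = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "P": 1.80,
    "K": 2.75,
}

_STANDARD_VALENCE = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "P": 3,
    "K": 1,
}


class ChemError(Exception):
    """Base class for structure-handling errors."""


class SmilesError(ChemError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MolfileError(ChemError):
    pass


class ElementError(ChemError):
    pass


class ValenceError(ChemError):
    pass


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    is_aromatic: bool = False
    coords: Optional[tuple[float, float, float]] = None
    # Explicit hydrogen count from a SMILES bracket, overriding the valence
    # model during hydrogen completion.  None = use the valence model.
    h_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise ElementError(f"unsupported element {self.element!r}")

    @property
    def vdw_radius(self) -> float:
        return VDW_RADIUS[self.element]


@dataclass
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 (aromatic)

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ChemError("bond connects an atom to itself")
        if self.order not in (1, 2, 3, 1.5):
            raise ChemError(f"unsupported bond order {self.order}")

    @property
    def is_aromatic(self) -> bool:
        return self.order == 1.5


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""
    hydrogens_explicit: bool = False

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemError(f"bond ({b.i},{b.j}) has out-of-range atom index")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ChemError(f"duplicate bond {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        """(atom index, bond order) pairs adjacent to atom *i*."""
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append((b.j, b.order))
            elif b.j == i:
                out.append((b.i, b.order))
        return out

    def adjacency(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append((b.j, b.order))
            adj[b.j].append((b.i, b.order))
        return adj

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def has_coords(self) -> bool:
        return len(self.atoms) > 0 and all(a.coords is not None for a in self.atoms)

    def bond_order_total(self) -> float:
        """Number of bonds counting bond orders (aromatic = 1.5)."""
        return sum(b.order for b in self.bonds)


@dataclass(frozen=True)
class Formula:
    counts: tuple[tuple[str, int], ...]  # sorted (element, count), counts > 0

    @staticmethod
    def from_counts(counts: dict[str, int]) -> "Formula":
        clean = {e: c for e, c in counts.items() if c}
        if not clean or sum(clean.values()) < 1:
            raise ChemError("formula must contain at least one atom")
        if any(c < 0 for c in clean.values()):
            raise ChemError("negative element count")
        return Formula(tuple(sorted(clean.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def total_atoms(self) -> int:
        return sum(c for _, c in self.counts)

    def hill(self) -> str:
        """Hill-order rendering: C, H, then remaining elements alphabetically."""
        d = self.as_dict()
        parts = []
        for e in ["C", "H"]:
            if e in d:
                parts.append(e + (str(d[e]) if d[e] > 1 else ""))
        for e in sorted(k for k in d if k not in ("C", "H")):
            parts.append(e + (str(d[e]) if d[e] > 1 else ""))
        return "".join(parts)

    def __add__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for e, c in other.counts:
            d[e] = d.get(e, 0) + c
        return Formula.from_counts(d)

    def __str__(self) -> str:
        return self.hill()


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a plain molecular formula string such as ``C21H22O6``."""
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ChemError(f"cannot parse formula {text!r} at position {pos}")
        elem = m.group(1)
        if elem not in SUPPORTED_ELEMENTS:
            raise ElementError(f"unsupported element {elem!r} in formula {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    return Formula.from_counts(counts)


# ---------------------------------------------------------------------------
# SMILES (subset) parsing
# ---------------------------------------------------------------------------

_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = ("C", "N", "O", "S", "F", "P")
_AROMATIC_ONE = ("c", "n", "o", "s")
_BRACKET_RE = re.compile(
    r"\[(?P<elem>[A-Z][a-z]?|[cnos])(?P<hcount>H\d*)?(?P<charge>[+-]\d*|\++|-+)?\]"
)


def parse_smiles(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string (defined subset) into a molecular graph.

    Supported: organic-subset atoms, aromatic lowercase atoms, brackets with
    charge and H count, branches, ring-closure digits (including %nn), and
    the bond symbols ``-``, ``=``, ``#``.  Stereo markers ``/ \\ @`` are
    accepted and ignored.  Implicit hydrogens are *not* materialized here.
    """
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    stack: list[int] = []
    prev: Optional[int] = None
    pending_order: Optional[float] = None
    ring_open: dict[int, tuple[int, Optional[float]]] = {}

    def close_or_open_ring(num: int, pos: int) -> None:
        nonlocal pending_order
        if prev is None:
            raise SmilesError("ring-closure digit before any atom", pos)
        if num in ring_open:
            other, order_there = ring_open.pop(num)
            order = pending_order if pending_order is not None else order_there
            if order is None:
                both_arom = atoms[other].is_aromatic and atoms[prev].is_aromatic
                order = 1.5 if both_arom else 1
            bonds.append(Bond(other, prev, order))
        else:
            ring_open[num] = (prev, pending_order)
        pending_order = None

    def attach(idx: int) -> None:
        nonlocal prev, pending_order
        if prev is not None:
            order = pending_order
            if order is None:
                both_arom = atoms[prev].is_aromatic and atoms[idx].is_aromatic
                order = 1.5 if both_arom else 1
            bonds.append(Bond(prev, idx, order))
        prev = idx
        pending_order = None

    pos = 0
    n = len(text)
    while pos < n:
        ch = text[pos]
        if ch in "/\\@":
            pos += 1
            continue
        if ch == "-":
            pending_order = 1
            pos += 1
        elif ch == "=":
            pending_order = 2
            pos += 1
        elif ch == "#":
            pending_order = 3
            pos += 1
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch opened before any atom", pos)
            stack.append(prev)
            pos += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unmatched closing parenthesis", pos)
            prev = stack.pop()
            pos += 1
        elif ch.isdigit():
            close_or_open_ring(int(ch), pos)
            pos += 1
        elif ch == "%":
            m = re.match(r"%(\d\d)", text[pos:])
            if not m:
                raise SmilesError("malformed %nn ring closure", pos)
            close_or_open_ring(int(m.group(1)), pos)
            pos += 3
        elif ch == "[":
            m = _BRACKET_RE.match(text, pos)
            if not m:
                raise SmilesError("malformed bracket atom", pos)
            raw = m.group("elem")
            aromatic = raw.islower()
            elem = raw.capitalize() if aromatic else raw
            if elem not in SUPPORTED_ELEMENTS:
                raise SmilesError(f"unsupported element {elem!r}", pos)
            hc = m.group("hcount")
            h_count = 0
            if hc is not None:
                h_count = int(hc[1:]) if len(hc) > 1 else 1
            charge = 0
            cg = m.group("charge")
            if cg:
                if cg in ("+", "-") or all(c == cg[0] for c in cg):
                    charge = len(cg) if cg[0] == "+" else -len(cg)
                if any(c.isdigit() for c in cg):
                    charge = int(cg[1:]) * (1 if cg[0] == "+" else -1)
            atoms.append(
                Atom(elem, formal_charge=charge, is_aromatic=aromatic, h_count=h_count)
            )
            attach(len(atoms) - 1)
            pos = m.end()
        elif text[pos : pos + 2] in _ORGANIC_TWO:
            atoms.append(Atom(text[pos : pos + 2]))
            attach(len(atoms) - 1)
            pos += 2
        elif ch in _ORGANIC_ONE:
            atoms.append(Atom(ch))
            attach(len(atoms) - 1)
            pos += 1
        elif ch in _AROMATIC_ONE:
            atoms.append(Atom(ch.upper(), is_aromatic=True))
            attach(len(atoms) - 1)
            pos += 1
        else:
            raise SmilesError(f"unsupported token {ch!r}", pos)

    if stack:
        raise SmilesError("unclosed branch", n)
    if ring_open:
        raise SmilesError(f"unclosed ring closure(s) {sorted(ring_open)}", n)
    if not atoms:
        raise SmilesError("empty SMILES", 0)
    return Molecule(atoms=atoms, bonds=bonds, name=name, hydrogens_explicit=False)


def read_smiles_file(stream: Iterable[str]) -> list[Molecule]:
    """Read ``smiles<TAB>id`` lines; ``#`` lines are comments."""
    mols = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else ""
        mols.append(parse_smiles(smiles, name=name))
    return mols


# ---------------------------------------------------------------------------
# MOL/SDF V2000 reading
# ---------------------------------------------------------------------------


def _parse_molblock(lines: Sequence[str]) -> Molecule:
    if len(lines) < 4:
        raise MolfileError("molblock shorter than header")
    name = lines[0].strip()
    counts = lines[3]
    if "V2000" not in counts:
        raise MolfileError("counts line does not declare V2000")
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except ValueError as exc:
        raise MolfileError(f"malformed counts line: {counts!r}") from exc
    if len(lines) < 4 + natoms + nbonds:
        raise MolfileError("molblock truncated")
    atoms: list[Atom] = []
    for k in range(natoms):
        line = lines[4 + k]
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            elem = line[31:34].strip()
        except ValueError as exc:
            raise MolfileError(f"malformed atom line {k + 1}: {line!r}") from exc
        if elem not in SUPPORTED_ELEMENTS:
            raise ElementError(f"unsupported element {elem!r} in molblock atom {k + 1}")
        atoms.append(Atom(elem, coords=(x, y, z)))
    bonds: list[Bond] = []
    for k in range(nbonds):
        line = lines[4 + natoms + k]
        try:
            i, j, t = int(line[0:3]) - 1, int(line[3:6]) - 1, int(line[6:9])
        except ValueError as exc:
            raise MolfileError(f"malformed bond line {k + 1}: {line!r}") from exc
        if t not in (1, 2, 3, 4):
            raise MolfileError(f"unsupported bond type {t} in bond line {k + 1}")
        order = 1.5 if t == 4 else float(t)
        if t == 4:
            atoms[i].is_aromatic = True
            atoms[j].is_aromatic = True
        bonds.append(Bond(i, j, order))
    for line in lines[4 + natoms + nbonds :]:
        if line.startswith("M  CHG"):
            fields = line.split()
            npairs = int(fields[2])
            for p in range(npairs):
                idx = int(fields[3 + 2 * p]) - 1
                atoms[idx].formal_charge = int(fields[4 + 2 * p])
    return Molecule(atoms=atoms, bonds=bonds, name=name, hydrogens_explicit=False)


def read_molfile(stream) -> list[Molecule]:
    """Read one or more V2000 records from a MOL/SDF text stream."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)
    mols = []
    record: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if record:
                mols.append(_parse_molblock(record))
            record = []
        else:
            record.append(line)
    if any(line.strip() for line in record):
        mols.append(_parse_molblock(record))
    if not mols:
        raise MolfileError("no molecule records found")
    return mols


# ---------------------------------------------------------------------------
# Hydrogen completion and formula/mass arithmetic
# ---------------------------------------------------------------------------


def _target_valence(atom: Atom) -> int:
    base = _STANDARD_VALENCE[atom.element]
    if atom.element == "C":
        v = base - abs(atom.formal_charge)
    else:
        v = base + atom.formal_charge
    return max(v, 0)


def add_hydrogens(mol: Molecule) -> Molecule:
    """Pad every heavy atom to its standard valence with explicit hydrogens.

    Valence model: single/double/triple bonds contribute their order; each
    aromatic bond contributes 1, plus 1 extra per aromatic atom for the ring
    closure of the delocalized system (so an aromatic carbon with two ring
    neighbors receives one hydrogen).  Bracket-atom H counts override the
    model.  See docs/valence-model.md for the truth table.
    """
    if mol.hydrogens_explicit:
        raise ChemError("hydrogens already explicit")
    atoms = [replace(a) for a in mol.atoms]
    bonds = list(mol.bonds)
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            continue
        if atom.h_count is not None:
            n_h = atom.h_count
        else:
            used = 0.0
            n_arom = 0
            for _, order in mol.neighbors(i):
                if order == 1.5:
                    used += 1
                    n_arom += 1
                else:
                    used += order
            if atom.is_aromatic and n_arom > 0:
                used += 1  # ring-membership closure of the aromatic system
            implicit = _target_valence(atom) - used
            if implicit < 0:
                if atom.is_aromatic:
                    implicit = 0
                else:
                    raise ValenceError(
                        f"atom {i} ({atom.element}) exceeds standard valence"
                    )
            n_h = int(round(implicit))
        for _ in range(n_h):
            atoms.append(Atom("H"))
            bonds.append(Bond(i, len(atoms) - 1, 1))
    return Molecule(
        atoms=atoms, bonds=bonds, name=mol.name, hydrogens_explicit=True
    )


def molecular_formula(mol: Molecule) -> Formula:
    if not mol.hydrogens_explicit:
        raise ChemError("hydrogens must be explicit before formula computation")
    counts: dict[str, int] = {}
    for a in mol.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
    return Formula.from_counts(counts)


def average_mw(f: Formula) -> float:
    """Average molecular weight (g/mol) from the fixed atomic weight table."""
    try:
        return sum(ATOMIC_WEIGHT[e] * c for e, c in f.counts)
    except KeyError as exc:
        raise ElementError(f"no atomic weight for element {exc}") from exc


def monoisotopic_mz(
    f: Formula,
    charge: int = 1,
    cation_adduct: Optional[str] = None,
) -> float:
    """Monoisotopic m/z of a singly charged ion.

    If *cation_adduct* (``"H"`` or ``"K"``) is given, *f* is the neutral
    molecular formula and the adduct mass is added.  Otherwise *f* is the
    formula of the ion itself.  One electron mass is subtracted per positive
    charge (added for negative).
    """
    if charge not in (1, -1):
        raise ChemError("only singly charged ions are supported (|charge| = 1)")
    try:
        mass = sum(MONOISOTOPIC_MASS[e] * c for e, c in f.counts)
    except KeyError as exc:
        raise ElementError(f"no monoisotopic mass for element {exc}") from exc
    if cation_adduct is not None:
        adduct = cation_adduct.rstrip("+")
        if adduct not in ("H", "K"):
            raise ChemError(f"unsupported cation adduct {cation_adduct!r}")
        if charge != 1:
            raise ChemError("cation adducts imply charge +1")
        mass += MONOISOTOPIC_MASS[adduct]
    return mass - charge * ELECTRON_MASS
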