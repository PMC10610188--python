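"""Sphere-point molecular surface areas (Shrake-Rupley style) with a
deterministic generalized-spiral point set; no randomness anywhere."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..chem import ChemError, Molecule


class GeometryError(ChemError):
    pass


@dataclass
class SurfaceAreas:
    per_atom: list[float]  # exposed area per atom (A^2)
    probe_radius: float
    n_sphere_points: int

    @property
    def tmsa(self) -> float:
        return float(sum(self.per_atom))


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on a generalized (golden) spiral."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(mol: Molecule, probe: float = 0.0, n_points: int = 960) -> SurfaceAreas:
    """Per-atom exposed surface area on spheres of radius r_vdw + probe.

    With probe = 0 this is the van der Waals surface; TMSA is the sum over
    atoms.  Each atom's sphere is sampled with *n_points* deterministic
    spiral points; a point is buried when it falls inside the inflated
    sphere of any other atom.
    """
    if not mol.has_coords():
        raise GeometryError("molecule has no coordinates")
    if n_points < 96:
        raise ValueError("n_points must be >= 96")
    coords = np.array([a.coords for a in mol.atoms], dtype=float)
    radii = np.array([a.vdw_radius + probe for a in mol.atoms], dtype=float)
    unit = sphere_points(n_points)
    n = len(mol.atoms)
    per_atom = []
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        # neighbors whose inflated sphere can reach atom i's surface
        d = np.linalg.norm(coords - coords[i], axis=1)
        nbr = np.where((d < radii + radii[i]) & (np.arange(n) != i))[0]
        exposed = np.ones(n_points, dtype=bool)
        for j in nbr:
            dist2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= dist2 >= radii[j] ** 2
        frac = exposed.sum() / n_points
        per_atom.append(frac * 4.0 * math.pi * radii[i] ** 2)
    return SurfaceAreas(per_atom=per_atom, probe_radius=probe, n_sphere_points=n_points)
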