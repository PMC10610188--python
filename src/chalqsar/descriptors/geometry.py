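"""Principal-axis alignment and shadow (projected vdW area) descriptors."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from ..chem import ATOMIC_WEIGHT, Molecule
from .surface import GeometryError
from .vector import DescriptorVector

_PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


def align_principal_axes(mol: Molecule) -> Molecule:
    """Return a copy with the conformer aligned to its principal axes.

    The mass-weighted centroid is moved to the origin and the axes are the
    eigenvectors of the mass-weighted covariance (inertia) tensor, reordered
    so the largest spatial extent lies along X, then Y.  Signs are fixed so
    the first atom with a non-zero component on each axis is positive.
    """
    if not mol.has_coords():
        raise GeometryError("molecule has no coordinates")
    coords = np.array([a.coords for a in mol.atoms], dtype=float)
    masses = np.array([ATOMIC_WEIGHT[a.element] for a in mol.atoms])
    centroid = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    centered = coords - centroid
    cov = (masses[:, None, None] * centered[:, :, None] * centered[:, None, :]).sum(
        axis=0
    ) / masses.sum()
    _, vecs = np.linalg.eigh(cov)
    rotated = centered @ vecs
    # order axes by decreasing spatial extent
    spans = rotated.max(axis=0) - rotated.min(axis=0)
    order = np.argsort(-spans, kind="stable")
    rotated = rotated[:, order]
    # deterministic sign convention
    for axis in range(3):
        col = rotated[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-8)[0]
        if nz.size and col[nz[0]] < 0:
            rotated[:, axis] = -col
    atoms = [
        replace(a, coords=tuple(float(x) for x in rotated[i]))
        for i, a in enumerate(mol.atoms)
    ]
    return Molecule(
        atoms=atoms,
        bonds=list(mol.bonds),
        name=mol.name,
        hydrogens_explicit=mol.hydrogens_explicit,
    )


def _shadow_area(u: np.ndarray, v: np.ndarray, r: np.ndarray, step: float) -> float:
    """Area of the union of disks (u, v, r) by grid rasterization."""
    umin, umax = float((u - r).min()), float((u + r).max())
    vmin, vmax = float((v - r).min()), float((v + r).max())
    nu = max(int(math.ceil((umax - umin) / step)), 1)
    nv = max(int(math.ceil((vmax - vmin) / step)), 1)
    covered = np.zeros((nu, nv), dtype=bool)
    for uk, vk, rk in zip(u, v, r):
        i0 = max(int((uk - rk - umin) / step) - 1, 0)
        i1 = min(int((uk + rk - umin) / step) + 2, nu)
        j0 = max(int((vk - rk - vmin) / step) - 1, 0)
        j1 = min(int((vk + rk - vmin) / step) + 2, nv)
        gu = umin + (np.arange(i0, i1) + 0.5) * step
        gv = vmin + (np.arange(j0, j1) + 0.5) * step
        du2 = (gu - uk)[:, None] ** 2
        dv2 = (gv - vk)[None, :] ** 2
        covered[i0:i1, j0:j1] |= du2 + dv2 <= rk * rk
    return float(covered.sum()) * step * step


def shadow_descriptors(mol: Molecule, grid_step: float = 0.02) -> DescriptorVector:
    """Projected vdW shadow areas and shadow/enclosing-rectangle ratios.

    The molecule must already be aligned (see :func:`align_principal_axes`);
    projections use the post-alignment coordinate axes.  For each plane the
    descriptor pair is the union-of-disks area S and S divided by the area
    of the enclosing rectangle (extents including radii).
    """
    if not mol.has_coords():
        raise GeometryError("molecule has no coordinates")
    if grid_step > 0.05:
        raise ValueError("grid_step must be <= 0.05 A")
    coords = np.array([a.coords for a in mol.atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in mol.atoms], dtype=float)
    vec = DescriptorVector()
    for plane, (iu, iv) in _PLANES.items():
        u, v = coords[:, iu], coords[:, iv]
        if len(mol.atoms) == 1:
            # closed form: one disk in its bounding square
            s = math.pi * radii[0] ** 2
            ratio = math.pi / 4.0
        else:
            s = _shadow_area(u, v, radii, grid_step)
            lu = float((u + radii).max() - (u - radii).min())
            lv = float((v + radii).max() - (v - radii).min())
            ratio = s / (lu * lv)
        vec.set(f"{plane}S", s)
        vec.set(f"{plane}S/{plane}R", ratio)
    return vec
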