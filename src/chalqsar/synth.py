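"""Synthetic inputs: seeded linear descriptor/activity datasets with known
ground truth, hand-coded toy molecules for analytic descriptor checks, and
randomized activity tables.

Every generator is a pure function of its arguments; the only RNG is
``numpy.random.default_rng(seed)``.  Descriptor computation itself is
RNG-free, so these are the only stochastic pieces of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityRecord, CELL_LINES, PotencyTable
from .chem import Atom, Bond, Molecule
from .qsar import DescriptorMatrix, QsarError

__all__ = [
    "SyntheticTruth",
    "gen_linear_dataset",
    "toy_molecules",
    "gen_activity_table",
]

# Mixed-sign magnitude pattern echoing the published model, including one
# ~1e-3 coefficient paired with a large-scale descriptor to stress
# numerical conditioning.
_DEFAULT_COEFFS = (-3.0874, 13.643, 4.6709, 1.0132e-3, 5.6120)
_DEFAULT_INTERCEPT = 5.0


@dataclass
class SyntheticTruth:
    coefficients: dict[str, float]
    intercept: float
    noise_sd: float
    n: int
    seed: int
    target_r2: float = 0.72
    descriptor_scales: dict[str, float] = field(default_factory=dict)


def gen_linear_dataset(
    n: int,
    true_terms: int = 5,
    decoy_terms: int = 45,
    target_r2: float = 0.72,
    seed: int = 0,
    decoy_rhos: tuple[float, ...] = (0.3,),
    n_factors: int = 2,
    idio: float = 0.12,
) -> tuple[DescriptorMatrix, np.ndarray, SyntheticTruth]:
    """Descriptor matrix following a known linear model plus decoys.

    True descriptors are i.i.d. Gaussians scaled so every term contributes
    unit signal variance; the noise SD is set so the population R2 equals
    *target_r2*.  The decoy pool mimics a real descriptor catalogue: for
    each value in *decoy_rhos* (supported range 0.3-0.95) one decoy per
    true term is correlated with it at that level, and the remaining decoys
    are drawn from a low-rank collinear cluster structure (*n_factors*
    latent factors with idiosyncratic noise fraction *idio*).  Returns
    (matrix, y, truth).
    """
    if not 0 < target_r2 < 1:
        raise QsarError("target_r2 must be in (0, 1)")
    if true_terms < 1:
        raise QsarError("need at least one true term")
    if any(not 0.3 <= r <= 0.95 for r in decoy_rhos):
        raise QsarError("decoy_rhos must lie in [0.3, 0.95]")
    if n < true_terms * 5:
        import warnings

        warnings.warn(
            f"n={n} violates the one-descriptor-per-five-molecules rule for "
            f"{true_terms} terms",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    coeffs = [
        _DEFAULT_COEFFS[i % len(_DEFAULT_COEFFS)] for i in range(true_terms)
    ]
    # descriptor sd_i = 1/|beta_i| gives unit signal contribution per term;
    # dividing by the signed coefficient keeps the published sign pattern
    scales = [1.0 / b for b in coeffs]
    true_names = [f"T{i + 1}" for i in range(true_terms)]
    raw_true = rng.standard_normal((n, true_terms))
    X_true = raw_true * np.array(scales)

    decoy_names = [f"D{i + 1:02d}" for i in range(decoy_terms)]
    decoy_cols = []
    factors = rng.standard_normal((n, n_factors))
    idio_norm = math.sqrt(1.0 + idio * idio)
    plan = [
        (j, rho) for rho in decoy_rhos for j in range(true_terms)
    ][:decoy_terms]
    for d in range(decoy_terms):
        base = (
            factors[:, d % n_factors] + idio * rng.standard_normal(n)
        ) / idio_norm
        if d < len(plan):
            j, rho = plan[d]
            base = rho * raw_true[:, j] + math.sqrt(1 - rho * rho) * base
        decoy_cols.append(base)

    signal_var = float(true_terms)  # unit contribution per term
    noise_sd = math.sqrt(signal_var * (1.0 - target_r2) / target_r2)
    y = (
        _DEFAULT_INTERCEPT
        + X_true @ np.array(coeffs)
        + noise_sd * rng.standard_normal(n)
    )

    ids = [f"mol{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(
        np.column_stack([X_true] + [c[:, None] for c in decoy_cols]),
        index=ids,
        columns=true_names + decoy_names,
    )
    matrix = DescriptorMatrix(
        data=frame, classes={c: "synthetic" for c in frame.columns}
    )
    truth = SyntheticTruth(
        coefficients=dict(zip(true_names, coeffs)),
        intercept=_DEFAULT_INTERCEPT,
        noise_sd=noise_sd,
        n=n,
        seed=seed,
        target_r2=target_r2,
        descriptor_scales=dict(zip(true_names, scales)),
    )
    return matrix, y, truth


def gen_activity_table(
    compound_ids: list[str], seed: int = 0, censor_fraction: float = 0.0
) -> PotencyTable:
    """Log-uniform GI50 values in [0.05, 30] uM across the three cell lines,
    with the stated fraction censored at the 30 uM assay ceiling."""
    if not 0 <= censor_fraction < 1:
        raise QsarError("censor_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for cid in compound_ids:
        for line in CELL_LINES:
            if rng.random() < censor_fraction:
                records.append(ActivityRecord(cid, line, 30.0, censored=True))
            else:
                gi50 = float(
                    10 ** rng.uniform(math.log10(0.05), math.log10(30.0))
                )
                records.append(ActivityRecord(cid, line, round(gi50, 3)))
    return PotencyTable(records=records)


# ---------------------------------------------------------------------------
# Toy molecules with hand-set conformers
# ---------------------------------------------------------------------------


def _mol(name, atoms, bonds):
    return Molecule(atoms=atoms, bonds=bonds, name=name, hydrogens_explicit=True)


def _ring_h(center: tuple, atom_xy: tuple, bond: float = 1.08) -> tuple:
    """Place a hydrogen radially outward from a planar ring atom."""
    dx, dy = atom_xy[0] - center[0], atom_xy[1] - center[1]
    norm = math.hypot(dx, dy)
    return (atom_xy[0] + bond * dx / norm, atom_xy[1] + bond * dy / norm, 0.0)


def toy_molecules() -> list[Molecule]:
    """Hand-coded molecules with exact conformers and explicit hydrogens:
    methane, ethane, methanol, benzene, thiophene, acetone, and
    4-chloroacetophenone."""
    mols = []

    t = 1.09 / math.sqrt(3.0)
    mols.append(
        _mol(
            "methane",
            [
                Atom("C", coords=(0.0, 0.0, 0.0)),
                Atom("H", coords=(t, t, t)),
                Atom("H", coords=(t, -t, -t)),
                Atom("H", coords=(-t, t, -t)),
                Atom("H", coords=(-t, -t, t)),
            ],
            [Bond(0, k, 1) for k in range(1, 5)],
        )
    )

    # staggered ethane along x
    cc = 1.54 / 2
    ch_ax, ch_r = 1.09 / 3.0, 1.09 * math.sqrt(8.0) / 3.0
    eth_atoms = [Atom("C", coords=(-cc, 0.0, 0.0)), Atom("C", coords=(cc, 0.0, 0.0))]
    eth_bonds = [Bond(0, 1, 1)]
    for k in range(3):
        ang = 2 * math.pi * k / 3
        eth_atoms.append(
            Atom("H", coords=(-cc - ch_ax, ch_r * math.cos(ang), ch_r * math.sin(ang)))
        )
        eth_bonds.append(Bond(0, len(eth_atoms) - 1, 1))
        ang2 = ang + math.pi / 3
        eth_atoms.append(
            Atom("H", coords=(cc + ch_ax, ch_r * math.cos(ang2), ch_r * math.sin(ang2)))
        )
        eth_bonds.append(Bond(1, len(eth_atoms) - 1, 1))
    mols.append(_mol("ethane", eth_atoms, eth_bonds))

    mols.append(
        _mol(
            "methanol",
            [
                Atom("C", coords=(0.0, 0.0, 0.0)),
                Atom("O", coords=(1.43, 0.0, 0.0)),
                Atom("H", coords=(1.76, 0.90, 0.0)),
                Atom("H", coords=(-0.36, -0.51, 0.89)),
                Atom("H", coords=(-0.36, -0.51, -0.89)),
                Atom("H", coords=(-0.36, 1.03, 0.0)),
            ],
            [Bond(0, 1, 1), Bond(1, 2, 1), Bond(0, 3, 1), Bond(0, 4, 1), Bond(0, 5, 1)],
        )
    )

    # regular benzene hexagon, C-C 1.39, C-H 1.09
    r_c = 1.39
    benz_atoms, benz_bonds = [], []
    for k in range(6):
        ang = math.pi * k / 3
        benz_atoms.append(
            Atom("C", is_aromatic=True, coords=(r_c * math.cos(ang), r_c * math.sin(ang), 0.0))
        )
    for k in range(6):
        benz_bonds.append(Bond(k, (k + 1) % 6, 1.5))
    for k in range(6):
        ang = math.pi * k / 3
        rr = r_c + 1.09
        benz_atoms.append(Atom("H", coords=(rr * math.cos(ang), rr * math.sin(ang), 0.0)))
        benz_bonds.append(Bond(k, 6 + k, 1))
    mols.append(_mol("benzene", benz_atoms, benz_bonds))

    # planar thiophene (approximate experimental geometry)
    s_xy = (0.0, 1.19)
    ring_xy = [(1.235, 0.33), (0.71, -0.98), (-0.71, -0.98), (-1.235, 0.33)]
    th_atoms = [Atom("S", is_aromatic=True, coords=(s_xy[0], s_xy[1], 0.0))]
    for xy in ring_xy:
        th_atoms.append(Atom("C", is_aromatic=True, coords=(xy[0], xy[1], 0.0)))
    th_bonds = [
        Bond(0, 1, 1.5),
        Bond(1, 2, 1.5),
        Bond(2, 3, 1.5),
        Bond(3, 4, 1.5),
        Bond(4, 0, 1.5),
    ]
    centroid = (0.0, (1.19 + 0.33 * 2 - 0.98 * 2) / 5.0)
    for k, xy in enumerate(ring_xy):
        th_atoms.append(Atom("H", coords=_ring_h(centroid, xy)))
        th_bonds.append(Bond(1 + k, len(th_atoms) - 1, 1))
    mols.append(_mol("thiophene", th_atoms, th_bonds))

    mols.append(
        _mol(
            "acetone",
            [
                Atom("C", coords=(0.0, 0.0, 0.0)),
                Atom("O", coords=(0.0, 1.22, 0.0)),
                Atom("C", coords=(1.29, -0.75, 0.0)),
                Atom("C", coords=(-1.29, -0.75, 0.0)),
                Atom("H", coords=(2.12, -0.06, 0.0)),
                Atom("H", coords=(1.35, -1.39, 0.88)),
                Atom("H", coords=(1.35, -1.39, -0.88)),
                Atom("H", coords=(-2.12, -0.06, 0.0)),
                Atom("H", coords=(-1.35, -1.39, 0.88)),
                Atom("H", coords=(-1.35, -1.39, -0.88)),
            ],
            [
                Bond(0, 1, 2),
                Bond(0, 2, 1),
                Bond(0, 3, 1),
                Bond(2, 4, 1),
                Bond(2, 5, 1),
                Bond(2, 6, 1),
                Bond(3, 7, 1),
                Bond(3, 8, 1),
                Bond(3, 9, 1),
            ],
        )
    )

    # 4-chloroacetophenone: planar ring + acetyl, methyl H out of plane
    rc = 1.39
    ring = []
    for k in range(6):
        ang = math.pi * k / 3
        ring.append((rc * math.cos(ang), rc * math.sin(ang)))
    atoms = [Atom("C", is_aromatic=True, coords=(x, y, 0.0)) for x, y in ring]
    bonds = [Bond(k, (k + 1) % 6, 1.5) for k in range(6)]
    # Cl on C3 (para), acetyl on C0 (ring[0] is at angle 0, ring[3] at 180)
    atoms.append(Atom("Cl", coords=(-(rc + 1.74), 0.0, 0.0)))
    bonds.append(Bond(3, 6, 1))
    # acetyl: carbonyl C, O, methyl C
    cco = rc + 1.49
    atoms.append(Atom("C", coords=(cco, 0.0, 0.0)))  # 7 carbonyl C
    bonds.append(Bond(0, 7, 1))
    atoms.append(Atom("O", coords=(cco + 0.61, 1.06, 0.0)))  # 8
    bonds.append(Bond(7, 8, 2))
    atoms.append(Atom("C", coords=(cco + 0.76, -1.32, 0.0)))  # 9 methyl C
    bonds.append(Bond(7, 9, 1))
    for k, (x, y) in enumerate(ring):
        if k in (0, 3):
            continue
        atoms.append(Atom("H", coords=_ring_h((0.0, 0.0), (x, y))))
        bonds.append(Bond(k, len(atoms) - 1, 1))
    for dx, dy, dz in ((1.04, -0.48, 0.0), (-0.52, -0.80, 0.88), (-0.52, -0.80, -0.88)):
        atoms.append(Atom("H", coords=(cco + 0.76 + dx, -1.32 + dy, dz)))
        bonds.append(Bond(9, len(atoms) - 1, 1))
    mols.append(_mol("4-chloroacetophenone", atoms, bonds))

    return mols
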