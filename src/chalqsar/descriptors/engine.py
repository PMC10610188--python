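"""Merge all descriptor families into one vector per molecule."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ..chem import Molecule
from .charges import electrostatic_descriptors, partial_charges
from .constitutional import constitutional_descriptors
from .cpsa import cpsa_descriptors
from .geometry import align_principal_axes, shadow_descriptors
from .surface import sasa
from .topology import information_content
from .vector import MISSING, DescriptorVector, descriptor_catalogue

log = logging.getLogger(__name__)


@dataclass
class DescriptorConfig:
    probe: float = 0.0
    n_points: int = 960
    grid_step: float = 0.02
    ic_normalizer: str = "bonds"  # "bonds" -> BIC = IC/log2(q); "atoms" variant
    families: tuple[str, ...] = (
        "constitutional",
        "topological",
        "electrostatic",
        "geometrical",
    )


def _missing_family(vec: DescriptorVector, klass: str) -> None:
    for name, k in descriptor_catalogue().items():
        if k == klass and name not in vec:
            vec.set(name, MISSING)


def compute_descriptor_vector(
    mol: Molecule, config: DescriptorConfig | None = None
) -> DescriptorVector:
    """Compute every registered descriptor family for *mol*.

    Families that cannot be computed (no conformer, missing charge
    parameters, ...) are downgraded to MISSING with a logged warning rather
    than raising.
    """
    cfg = config or DescriptorConfig()
    vec = DescriptorVector()

    if "constitutional" in cfg.families:
        vec.update(constitutional_descriptors(mol))

    if "topological" in cfg.families:
        for k in (0, 1, 2):
            try:
                ic, bic = information_content(mol, k, normalizer=cfg.ic_normalizer)
                vec.set(f"IC{k}", ic)
                vec.set(f"BIC{k}", bic)
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("%s: IC order %d failed: %s", mol.name, k, exc)
                vec.set(f"IC{k}", MISSING)
                vec.set(f"BIC{k}", MISSING)
        vec.set("ABIC2", vec.get("BIC2"))

    charges = None
    if "electrostatic" in cfg.families:
        try:
            charges = partial_charges(mol)
            vec.update(electrostatic_descriptors(mol, charges))
        except Exception as exc:
            log.warning("%s: charge model unavailable: %s", mol.name, exc)
            _missing_family(vec, "electrostatic")

    if "geometrical" in cfg.families:
        if mol.has_coords():
            try:
                aligned = align_principal_axes(mol)
                vec.update(shadow_descriptors(aligned, grid_step=cfg.grid_step))
                # SASA on the aligned conformer: the deterministic sphere
                # point set then sees a canonical orientation, making the
                # surface (and CPSA) invariant under rigid motion of the input
                areas = sasa(aligned, probe=cfg.probe, n_points=cfg.n_points)
                vec.set("TMSA", areas.tmsa)
                if charges is not None:
                    vec.update(cpsa_descriptors(charges, areas))
                else:
                    _missing_family(vec, "electrostatic")
            except Exception as exc:
                log.warning("%s: geometric family failed: %s", mol.name, exc)
                _missing_family(vec, "geometrical")
                _missing_family(vec, "electrostatic")
        else:
            log.warning("%s: no conformer; geometric descriptors MISSING", mol.name)
            _missing_family(vec, "geometrical")
            # CPSA needs areas, so the surface-weighted names stay MISSING
            _missing_family(vec, "electrostatic")
    return vec
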