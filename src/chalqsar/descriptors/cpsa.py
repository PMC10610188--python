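"""Charged partial surface area (CPSA) descriptors.

With P the atoms carrying positive partial charge and N the negative ones:

* PPSA1 = sum of P areas; PPSA2 = (total positive charge) * PPSA1;
  PPSA3 = sum over P of charge * area.  PNSA1-3 mirror these for N.
* TMSA = total molecular surface area (all atoms).
* WPSA-k = PPSA-k * TMSA / 1000; WPSA-2 is emitted under its published
  descriptor name ``WPSA-2-W-PPSA``.
"""

from __future__ import annotations

from .charges import ChargeSet
from .surface import SurfaceAreas
from .vector import DescriptorVector


def cpsa_descriptors(charges: ChargeSet, areas: SurfaceAreas) -> DescriptorVector:
    if len(charges.values) != len(areas.per_atom):
        raise ValueError("charge set and surface areas have different atom counts")
    q = charges.values
    a = areas.per_atom
    tmsa = sum(a)
    ppsa1 = sum(ai for qi, ai in zip(q, a) if qi > 0)
    ppsa2 = sum(qi for qi in q if qi > 0) * ppsa1
    ppsa3 = sum(qi * ai for qi, ai in zip(q, a) if qi > 0)
    pnsa1 = sum(ai for qi, ai in zip(q, a) if qi < 0)
    pnsa2 = sum(qi for qi in q if qi < 0) * pnsa1
    pnsa3 = sum(qi * ai for qi, ai in zip(q, a) if qi < 0)
    vec = DescriptorVector()
    vec.set("TMSA", tmsa)
    vec.set("PPSA1", ppsa1)
    vec.set("PPSA2", ppsa2)
    vec.set("PPSA3", ppsa3)
    vec.set("PNSA1", pnsa1)
    vec.set("PNSA2", pnsa2)
    vec.set("PNSA3", pnsa3)
    vec.set("WPSA-1", ppsa1 * tmsa / 1000.0)
    vec.set("WPSA-2-W-PPSA", ppsa2 * tmsa / 1000.0)
    vec.set("WPSA-3", ppsa3 * tmsa / 1000.0)
    return vec
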