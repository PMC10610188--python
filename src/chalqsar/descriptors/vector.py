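"""Descriptor vector container and the registered descriptor catalogue."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Sentinel for an undefined descriptor value (e.g. MPCO with no oxygen).
MISSING = None

_ELEMENTS_COUNTED = ("C", "H", "N", "O", "S", "F", "Cl", "Br")

_CATALOGUE: dict[str, str] = {}


def _register(name: str, klass: str) -> str:
    _CATALOGUE[name] = klass
    return name


# constitutional
for _e in _ELEMENTS_COUNTED:
    _register(f"n_{_e}", "constitutional")
    _register(f"rel_n_{_e}", "constitutional")
_register("RNSA", "constitutional")  # relative number of sulfur atoms
for _n in ("n_atoms", "n_heavy", "MW", "Fsp3", "RB", "HBA", "HBD", "Far"):
    _register(_n, "constitutional")

# topological information content
for _k in (0, 1, 2):
    _register(f"IC{_k}", "topological")
    _register(f"BIC{_k}", "topological")
_register("ABIC2", "topological")  # average bonding information content, order 2

# electrostatic (partial charges + CPSA family)
for _n in ("MPCO", "max_pos_charge", "min_charge"):
    _register(_n, "electrostatic")
for _k in (1, 2, 3):
    _register(f"PPSA{_k}", "electrostatic")
    _register(f"PNSA{_k}", "electrostatic")
_register("WPSA-1", "electrostatic")
_register("WPSA-2-W-PPSA", "electrostatic")  # WPSA-2 = PPSA2 * TMSA / 1000
_register("WPSA-3", "electrostatic")

# geometrical
_register("TMSA", "geometrical")
for _p in ("XY", "XZ", "YZ"):
    _register(f"{_p}S", "geometrical")
    _register(f"{_p}S/{_p}R", "geometrical")


def descriptor_catalogue() -> dict[str, str]:
    """Mapping descriptor name -> family class for every registered name."""
    return dict(_CATALOGUE)


@dataclass
class DescriptorVector:
    """Named descriptor values for one molecule; ``None`` marks MISSING."""

    values: dict[str, Optional[float]] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: Optional[float]) -> None:
        if name not in _CATALOGUE:
            raise KeyError(f"descriptor {name!r} is not in the registered catalogue")
        self.values[name] = value
        self.classes[name] = _CATALOGUE[name]

    def get(self, name: str) -> Optional[float]:
        return self.values.get(name, MISSING)

    def update(self, other: "DescriptorVector") -> None:
        self.values.update(other.values)
        self.classes.update(other.classes)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __len__(self) -> int:
        return len(self.values)
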