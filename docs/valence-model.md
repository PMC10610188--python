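# Hydrogen-completion valence model

Each heavy atom is padded with explicit hydrogens up to its standard valence
(C 4, N 3, O 2, S 2, F/Cl/Br 1, P 3), adjusted by formal charge (N/O/P:
base + charge; C: base − |charge|).  Bond contributions:

* single/double/triple bonds count their order (1/2/3);
* each **aromatic** bond counts 1, plus **one extra unit per aromatic atom**
  for the ring closure of the delocalized system.

A SMILES bracket H count (`[nH]`, `[OH2]`) overrides the model for that atom.
Negative implicit counts raise a valence error for non-aromatic atoms and are
clamped to zero for aromatic ones (e.g. thiophene sulfur).

## Truth table

| atom | context                                   | used = Σbonds (+1 arom.) | implicit H |
|------|-------------------------------------------|--------------------------|------------|
| C    | methane `C`                               | 0                        | 4          |
| C    | aromatic, 2 ring neighbors (`c1ccccc1`)   | 2 + 1 = 3                | 1          |
| C    | aromatic, 2 ring + 1 substituent          | 3 + 1 = 4                | 0          |
| C    | aromatic, 3 ring neighbors (fusion)       | 3 + 1 = 4                | 0          |
| C    | carbonyl C in `C=O`                       | 2                        | 2          |
| N    | aromatic, 2 ring neighbors (pyridine `n`) | 2 + 1 = 3                | 0          |
| N    | `[nH]` (pyrrole)                          | bracket override         | 1          |
| O    | water `O`                                 | 0                        | 2          |
| O    | aromatic, 2 ring neighbors (furan `o`)    | 2 + 1 = 3 → clamp        | 0          |
| S    | aromatic, 2 ring neighbors (thiophene `s`)| 2 + 1 = 3 → clamp        | 0          |
| O    | `[O-]`                                    | valence 2 − 1 = 1        | 1 − Σbonds |
| N    | `[N+]` quaternary                         | valence 3 + 1 = 4        | 4 − Σbonds |

Note: the +1 aromatic ring-closure unit is applied once per atom, not per
aromatic bond, so it reproduces Kekulé valences without aromaticity
perception.
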