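# chalqsar

A tested, reusable pipeline for 2D-QSAR analysis of antiproliferative
chalcones and diarylpentanoids: molecular structure handling and exact-mass
arithmetic, CODESSA-class descriptor computation, GI50 activity tables with
selectivity indices, heuristic multilinear-regression model building with
leave-one-out validation, and synthetic data generators that make every
stage testable offline.

## Components

| module | what it does |
|---|---|
| `chalqsar.chem` | SMILES-subset / MOL-SDF V2000 parsing, hydrogen completion, Hill formulas, average MW and monoisotopic m/z (H+/K+ adducts) |
| `chalqsar.descriptors` | constitutional counts (RNSA, Fsp3, RB, HBA/HBD), neighborhood-symmetry information content (ABIC2), PEOE partial charges (MPCO), spiral-point molecular surface + CPSA family (WPSA-2), principal-axis shadow indices (XYS/XYR) |
| `chalqsar.activity` | GI50 tables, pGI50 = 6 − log10(GI50/µM), selectivity indices SI1/SI2, censoring (">30") |
| `chalqsar.qsar` | descriptor prefiltering, OLS with standard errors, F statistic, hat-matrix LOO PRESS/Q², forward beam search capped at one term per five molecules, the published five-descriptor model evaluator |
| `chalqsar.synth` | seeded linear datasets with known truth + collinear decoys, hand-coded toy molecules, random activity tables |
| `chalqsar.pipeline` / `chalqsar.cli` | end-to-end orchestration with deterministic JSON reports |

## CLI

```sh
chalqsar descriptors --in fixtures/compounds_3d.sdf --out descriptors.csv
chalqsar fit --descriptors descriptors.csv --activity fixtures/activity_table1.csv \
    --line HCT116_p53_wt --report model.json
chalqsar predict --model eq1 --descriptors descriptors.csv
chalqsar validate --model model.json --descriptors descriptors.csv \
    --activity fixtures/activity_table1.csv
chalqsar mass --formula C27H34O6 --adduct K
chalqsar simulate linear --seed 1 --out sim/
chalqsar pipeline --config pipeline.yml
```

`pipeline.yml` keys: `structures` (or `descriptors_csv`), `activity`,
`cell_line`, `out_dir`, `test_size`, and nested `heuristic`
(`variance_min`, `alpha_single`, `r_max_pair`, `beam_width`, `max_terms`,
`seed`) and `descriptors` (`probe`, `n_points`, `grid_step`) sections.
Reruns with the same configuration produce byte-identical reports.

## Fixtures

`fixtures/compounds.smi` holds the study's compound structures transcribed
from their systematic names; `fixtures/compounds_3d.sdf` adds one embedded
3D conformer each (regenerate with `python scripts/make_fixtures.py`,
requires RDKit); `fixtures/activity_table1.csv` holds the printed GI50
values.  Each file carries a provenance header.
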