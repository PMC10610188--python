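"""Regenerate fixtures/compounds_3d.sdf from fixtures/compounds.smi.

Development-time script (run once, output committed): embeds a single 3D
conformer per compound with RDKit ETKDG at a fixed seed, adds explicit
hydrogens, and writes a V2000 SDF with aromatic bonds encoded as type 4 so
the package's own reader recovers aromaticity without perception.

Usage: python scripts/make_fixtures.py
"""

from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

ROOT = Path(__file__).resolve().parent.parent
HEADER = (
    "Structures transcribed from the systematic names in the synthesis\n"
    "section of the source study; 3D coordinates embedded once with RDKit\n"
    "ETKDGv3 (seed 20230901) and MMFF-optimized.  See compounds.smi.\n"
)


def main() -> None:
    lines = (ROOT / "fixtures" / "compounds.smi").read_text().splitlines()
    blocks = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, cid = line.split("\t")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SystemExit(f"RDKit rejected SMILES for compound {cid}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = 20230901
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise SystemExit(f"embedding failed for compound {cid}")
        AllChem.MMFFOptimizeMolecule(mol)
        mol.SetProp("_Name", cid)
        block = Chem.MolToMolBlock(mol, kekulize=False)
        blocks.append(block + "$$$$\n")
    out = ROOT / "fixtures" / "compounds_3d.sdf"
    out.write_text("".join(blocks))
    print(f"wrote {len(blocks)} records to {out}")


if __name__ == "__main__":
    main()
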