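from pathlib import Path

import pytest

from chalqsar.chem import add_hydrogens, read_molfile, read_smiles_file

ROOT = Path(__file__).resolve().parent.parent
FIXTURES = ROOT / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def smiles_molecules():
    """Paper compounds parsed from the SMILES fixture, hydrogens implicit."""
    text = (FIXTURES / "compounds.smi").read_text()
    return {m.name: m for m in read_smiles_file(text.splitlines())}


@pytest.fixture(scope="session")
def sdf_molecules():
    """Paper compounds from the 3D SDF fixture, hydrogens made explicit."""
    mols = read_molfile((FIXTURES / "compounds_3d.sdf").read_text())
    return {m.name: add_hydrogens(m) for m in mols}


@pytest.fixture(scope="session")
def toy():
    from chalqsar.synth import toy_molecules

    return {m.name: m for m in toy_molecules()}
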