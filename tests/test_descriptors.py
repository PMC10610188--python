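import math
from dataclasses import replace

import numpy as np
import pytest

from chalqsar.chem import Atom, Molecule, add_hydrogens, parse_smiles
from chalqsar.descriptors import (
    MISSING,
    ChargeSet,
    DescriptorConfig,
    SurfaceAreas,
    align_principal_axes,
    atom_classes,
    compute_descriptor_vector,
    constitutional_descriptors,
    cpsa_descriptors,
    electrostatic_descriptors,
    information_content,
    partial_charges,
    sasa,
    shadow_descriptors,
)
from chalqsar.descriptors.charges import ChargeModelError


def _rotate(mol, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return Molecule(
        atoms=[replace(a, coords=tuple(q @ np.array(a.coords))) for a in mol.atoms],
        bonds=list(mol.bonds),
        name=mol.name,
        hydrogens_explicit=mol.hydrogens_explicit,
    )


class TestConstitutional:
    def test_benzene(self, toy):
        vec = constitutional_descriptors(toy["benzene"])
        assert vec.get("RNSA") == 0.0
        assert vec.get("Fsp3") == 0.0
        assert vec.get("Far") == 1.0

    def test_thiophene_rnsa(self, toy):
        assert constitutional_descriptors(toy["thiophene"]).get("RNSA") == pytest.approx(
            1 / 9
        )

    def test_compound16_rnsa(self, sdf_molecules):
        vec = constitutional_descriptors(sdf_molecules["16"])
        assert vec.get("RNSA") == pytest.approx(1 / 30)

    def test_hba_hbd(self):
        mol = add_hydrogens(parse_smiles("OCCN"))
        vec = constitutional_descriptors(mol)
        assert vec.get("HBA") == 2  # one O + one N
        assert vec.get("HBD") == 3  # O-H plus two N-H

    def test_rotatable_bonds_butane(self):
        vec = constitutional_descriptors(add_hydrogens(parse_smiles("CCCC")))
        assert vec.get("RB") == 1

    def test_rotatable_bonds_exclude_ring_and_amide(self):
        ring = constitutional_descriptors(add_hydrogens(parse_smiles("C1CCCCC1")))
        assert ring.get("RB") == 0
        amide = constitutional_descriptors(add_hydrogens(parse_smiles("CC(=O)NC")))
        assert amide.get("RB") == 0

    def test_fsp3(self):
        vec = constitutional_descriptors(add_hydrogens(parse_smiles("CCc1ccccc1")))
        assert vec.get("Fsp3") == pytest.approx(2 / 8)


class TestAtomClasses:
    def test_benzene_order0(self, toy):
        assert atom_classes(toy["benzene"], 0).n_classes() == 2

    def test_methanol_refinement(self, toy):
        assert atom_classes(toy["methanol"], 0).n_classes() == 3
        assert atom_classes(toy["methanol"], 1).n_classes() == 4

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(C)C", "O=CC=O"])
    def test_nondecreasing_in_k(self, smiles):
        mol = add_hydrogens(parse_smiles(smiles))
        counts = [atom_classes(mol, k).n_classes() for k in range(4)]
        assert counts == sorted(counts)

    def test_labels_invariant_under_reindexing(self):
        a = add_hydrogens(parse_smiles("CCO"))
        b = add_hydrogens(parse_smiles("OCC"))
        assert sorted(atom_classes(a, 2).sizes()) == sorted(atom_classes(b, 2).sizes())


class TestInformationContent:
    def test_methane(self, toy):
        ic, bic = information_content(toy["methane"], 0)
        assert ic == pytest.approx(0.7219, abs=1e-4)
        assert bic == pytest.approx(0.3610, abs=1e-4)

    def test_benzene(self, toy):
        ic, bic = information_content(toy["benzene"], 0)
        assert ic == pytest.approx(1.0)
        # q = 6*1.5 + 6*1 = 15
        assert bic == pytest.approx(1 / math.log2(15), abs=1e-4)
        assert bic == pytest.approx(0.2560, abs=1e-4)

    def test_ethane(self, toy):
        ic, _ = information_content(toy["ethane"], 0)
        assert ic == pytest.approx(0.8113, abs=1e-4)

    def test_single_bond_missing(self):
        h2 = add_hydrogens(parse_smiles("[OH2]"))  # q = 2 > 1, fine
        _, bic = information_content(h2, 0)
        assert bic is not MISSING
        single = Molecule(
            atoms=[Atom("H"), Atom("H")],
            bonds=[__import__("chalqsar.chem", fromlist=["Bond"]).Bond(0, 1, 1)],
            hydrogens_explicit=True,
        )
        _, bic = information_content(single, 0)
        assert bic is MISSING  # q = 1 -> log2 q = 0

    def test_atoms_normalizer_variant(self, toy):
        ic, bic = information_content(toy["benzene"], 0, normalizer="atoms")
        assert bic == pytest.approx(ic / math.log2(12))

    def _brute_force_ic(self, mol, k):
        # independent oracle: recursive depth-k neighborhood signatures
        adj = mol.adjacency()

        def sig(i, depth):
            if depth == 0:
                return mol.atoms[i].element
            return (
                mol.atoms[i].element,
                tuple(sorted((order, sig(j, depth - 1)) for j, order in adj[i])),
            )

        sigs = [sig(i, k) for i in range(len(mol.atoms))]
        n = len(sigs)
        ent = 0.0
        for s in set(sigs):
            p = sigs.count(s) / n
            ent -= p * math.log2(p)
        return ent

    @pytest.mark.parametrize(
        "smiles", ["C", "CC", "CO", "C=O", "CC(C)O", "c1ccccc1", "CC#N", "OCC=O"]
    )
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_ic_matches_brute_force(self, smiles, k):
        mol = add_hydrogens(parse_smiles(smiles))
        assert len(mol.atoms) <= 12
        ic, _ = information_content(mol, k)
        assert ic == pytest.approx(self._brute_force_ic(mol, k), abs=1e-10)


class TestPartialCharges:
    def test_methane_symmetry_and_conservation(self, toy):
        ch = partial_charges(toy["methane"])
        hs = ch.values[1:]
        assert max(hs) - min(hs) < 1e-12
        assert abs(ch.total()) < 1e-6

    def test_formaldehyde_signs(self):
        mol = add_hydrogens(parse_smiles("C=O"))
        ch = partial_charges(mol)
        q = dict(zip((a.element for a in mol.atoms), ch.values))
        assert q["O"] < 0 < q["C"]

    def test_chlorobenzene_conservation(self):
        ch = partial_charges(add_hydrogens(parse_smiles("Clc1ccccc1")))
        assert abs(ch.total()) < 1e-6

    def test_charged_species_conservation(self):
        mol = add_hydrogens(parse_smiles("[NH4+]"))
        ch = partial_charges(mol)
        assert ch.total() == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_equivalent_atoms_equal(self, toy):
        mol = toy["benzene"]
        ch = partial_charges(mol)
        carbons = [q for a, q in zip(mol.atoms, ch.values) if a.element == "C"]
        assert max(carbons) - min(carbons) < 1e-6

    def test_missing_parameters(self):
        mol = add_hydrogens(parse_smiles("[K+]"))
        with pytest.raises(ChargeModelError):
            partial_charges(mol)


class TestElectrostatic:
    def test_no_oxygen_missing(self, toy):
        ch = partial_charges(toy["methane"])
        assert electrostatic_descriptors(toy["methane"], ch).get("MPCO") is MISSING

    def test_acetone_mpco_negative(self, toy):
        ch = partial_charges(toy["acetone"])
        assert electrostatic_descriptors(toy["acetone"], ch).get("MPCO") < 0

    def test_mpco_is_minimum(self):
        mol = add_hydrogens(parse_smiles("COC(=O)C"))
        ch = partial_charges(mol)
        mpco = electrostatic_descriptors(mol, ch).get("MPCO")
        oxy = [q for a, q in zip(mol.atoms, ch.values) if a.element == "O"]
        assert all(mpco <= q + 1e-15 for q in oxy)


class TestSasa:
    def test_isolated_atom_analytic(self):
        solo = Molecule(atoms=[Atom("C", coords=(0, 0, 0))], hydrogens_explicit=True)
        s = sasa(solo, probe=0.0, n_points=960)
        assert s.tmsa == pytest.approx(4 * math.pi * 1.70**2, rel=1e-9)

    def test_distant_atoms_no_occlusion(self):
        duo = Molecule(
            atoms=[Atom("C", coords=(0, 0, 0)), Atom("O", coords=(10, 0, 0))],
            hydrogens_explicit=True,
        )
        s = sasa(duo, probe=0.0, n_points=960)
        full = 4 * math.pi * (1.70**2 + 1.52**2)
        assert s.tmsa == pytest.approx(full, rel=1e-9)

    def test_two_sphere_cap_formula(self):
        r, d = 1.70, 2.0
        duo = Molecule(
            atoms=[Atom("C", coords=(0, 0, 0)), Atom("C", coords=(d, 0, 0))],
            hydrogens_explicit=True,
        )
        s = sasa(duo, probe=0.0, n_points=960)
        h = r - d / 2
        analytic = 2 * (4 * math.pi * r * r - 2 * math.pi * r * h)
        assert abs(s.tmsa - analytic) / analytic < 0.01

    def test_convergence(self, toy):
        mol = toy["acetone"]
        t1 = sasa(mol, 0.0, 960).tmsa
        t2 = sasa(mol, 0.0, 3840).tmsa
        assert abs(t1 - t2) / t2 < 0.005

    def test_per_atom_nonnegative_sum(self, toy):
        s = sasa(toy["thiophene"], 0.0, 960)
        assert all(a >= 0 for a in s.per_atom)
        assert s.tmsa == pytest.approx(sum(s.per_atom))

    def test_missing_coords(self):
        with pytest.raises(Exception):
            sasa(add_hydrogens(parse_smiles("C")), 0.0, 960)


class TestCpsa:
    def test_hand_arithmetic(self):
        charges = ChargeSet(values=[0.2, -0.2])
        areas = SurfaceAreas(per_atom=[30.0, 50.0], probe_radius=0.0, n_sphere_points=960)
        vec = cpsa_descriptors(charges, areas)
        assert vec.get("PPSA1") == pytest.approx(30.0)
        assert vec.get("PPSA2") == pytest.approx(6.0)
        assert vec.get("TMSA") == pytest.approx(80.0)
        assert vec.get("WPSA-2-W-PPSA") == pytest.approx(0.48)

    def test_all_negative(self):
        vec = cpsa_descriptors(
            ChargeSet(values=[-0.1, -0.3]),
            SurfaceAreas(per_atom=[10.0, 20.0], probe_radius=0.0, n_sphere_points=960),
        )
        assert vec.get("PPSA1") == vec.get("PPSA2") == vec.get("PPSA3") == 0.0

    def test_ppsa3(self):
        vec = cpsa_descriptors(
            ChargeSet(values=[0.1, 0.3]),
            SurfaceAreas(per_atom=[10.0, 20.0], probe_radius=0.0, n_sphere_points=960),
        )
        assert vec.get("PPSA3") == pytest.approx(7.0)

    def test_wpsa_identity(self, toy):
        mol = toy["acetone"]
        ch = partial_charges(mol)
        areas = sasa(mol, 0.0, 960)
        vec = cpsa_descriptors(ch, areas)
        assert vec.get("WPSA-2-W-PPSA") == pytest.approx(
            vec.get("PPSA2") * vec.get("TMSA") / 1000.0, rel=1e-12
        )


class TestAlignment:
    def test_diatomic_on_x_axis(self):
        duo = Molecule(
            atoms=[Atom("C", coords=(1.0, 2.0, 2.5)), Atom("C", coords=(2.0, 3.0, 4.0))],
            hydrogens_explicit=True,
        )
        aligned = align_principal_axes(duo)
        for a in aligned.atoms:
            assert abs(a.coords[1]) < 1e-9
            assert abs(a.coords[2]) < 1e-9

    def test_planar_in_xy(self, toy):
        aligned = align_principal_axes(toy["benzene"])
        assert max(abs(a.coords[2]) for a in aligned.atoms) < 1e-6

    def test_rotation_invariance(self, toy):
        mol = toy["4-chloroacetophenone"]
        a1 = align_principal_axes(mol)
        a2 = align_principal_axes(_rotate(mol, seed=5))
        for p, q in zip(a1.atoms, a2.atoms):
            assert np.allclose(p.coords, q.coords, atol=1e-6)


class TestShadow:
    def test_single_atom_closed_form(self):
        solo = Molecule(atoms=[Atom("C", coords=(0, 0, 0))], hydrogens_explicit=True)
        vec = shadow_descriptors(solo)
        assert vec.get("XYS/XYR") == pytest.approx(math.pi / 4)

    def test_two_touching_disks(self):
        # centers 2r apart: union area 2*pi*r^2 in a 4r x 2r rectangle
        r = 1.70
        duo = Molecule(
            atoms=[Atom("C", coords=(0, 0, 0)), Atom("C", coords=(2 * r, 0, 0))],
            hydrogens_explicit=True,
        )
        vec = shadow_descriptors(align_principal_axes(duo), grid_step=0.02)
        assert vec.get("XYS/XYR") == pytest.approx(math.pi / 4, rel=0.002)

    def test_duplicate_atoms_idempotent(self):
        one = Molecule(atoms=[Atom("C", coords=(0, 0, 0))], hydrogens_explicit=True)
        two = Molecule(
            atoms=[Atom("C", coords=(0, 0, 0)), Atom("C", coords=(0, 0, 0))],
            hydrogens_explicit=True,
        )
        s1 = shadow_descriptors(one).get("XYS")
        s2 = shadow_descriptors(two, grid_step=0.02).get("XYS")
        assert s2 == pytest.approx(s1, rel=0.002)

    def test_grid_convergence(self, toy):
        mol = align_principal_axes(toy["acetone"])
        a = shadow_descriptors(mol, grid_step=0.02).get("XYS/XYR")
        b = shadow_descriptors(mol, grid_step=0.01).get("XYS/XYR")
        assert abs(a - b) / b < 0.002

    def test_step_cap(self, toy):
        with pytest.raises(ValueError):
            shadow_descriptors(align_principal_axes(toy["acetone"]), grid_step=0.1)

    def test_ratio_bounds(self, sdf_molecules):
        mol = align_principal_axes(sdf_molecules["16"])
        vec = shadow_descriptors(mol)
        for plane in ("XY", "XZ", "YZ"):
            assert 0 < vec.get(f"{plane}S/{plane}R") <= 1


class TestVectorMerging:
    def test_benzene_catalogue(self, toy):
        vec = compute_descriptor_vector(toy["benzene"])
        assert vec.get("ABIC2") is not MISSING
        assert vec.get("RNSA") == 0.0
        assert vec.get("XYS/XYR") is not MISSING
        assert vec.get("WPSA-2-W-PPSA") is not MISSING
        assert vec.get("MPCO") is MISSING  # no oxygen

    def test_no_conformer_geometric_missing(self):
        mol = add_hydrogens(parse_smiles("CCO"))
        vec = compute_descriptor_vector(mol)
        assert vec.get("XYS/XYR") is MISSING
        assert vec.get("TMSA") is MISSING
        assert vec.get("MPCO") is not MISSING  # graph-only family still works

    def test_compound16_all_eq1_descriptors(self, sdf_molecules):
        vec = compute_descriptor_vector(sdf_molecules["16"])
        for name in ("ABIC2", "RNSA", "XYS/XYR", "WPSA-2-W-PPSA", "MPCO"):
            assert vec.get(name) is not MISSING, name

    def test_reindexing_invariance(self):
        a = compute_descriptor_vector(add_hydrogens(parse_smiles("CC(=O)c1ccc(Cl)cc1")))
        b = compute_descriptor_vector(add_hydrogens(parse_smiles("Clc1ccc(cc1)C(C)=O")))
        for name in ("ABIC2", "RNSA", "Fsp3", "HBA", "MPCO"):
            assert a.get(name) == pytest.approx(b.get(name), abs=1e-9), name


class TestRigidMotionInvariance:
    def test_shadow_and_cpsa_invariant(self, toy):
        mol = toy["4-chloroacetophenone"]
        rot = _rotate(mol, seed=11)
        v1 = compute_descriptor_vector(mol)
        v2 = compute_descriptor_vector(rot)
        for name in ("XYS/XYR", "TMSA", "WPSA-2-W-PPSA", "MPCO", "ABIC2"):
            assert v1.get(name) == pytest.approx(v2.get(name), abs=1e-6), name
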