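"""Kabsch superposition, dihedrals/Ramachandran, coordination, trajectories."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gelswap.conformation import (
    classify_rama,
    coordination_site,
    dihedral,
    dihedrals,
    pair_ca_by_number,
    superpose_kabsch,
    trajectory_rmsd,
)
from gelswap.structure import Atom, Chain, Residue, Selection, StructureModel


def _random_cloud(n: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).normal(0, 5, size=(n, 3))


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = _random_cloud(10, 0)
        res = superpose_kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered_exactly(self):
        pts = _random_cloud(12, 1)
        rot = Rotation.from_euler("xyz", [40, -25, 110], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -7.0, 2.0])
        res = superpose_kabsch(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.apply(pts), moved, atol=1e-8)

    def test_rmsd_symmetric_and_motion_invariant(self):
        a = _random_cloud(9, 2)
        b = a + np.random.default_rng(3).normal(0, 0.5, a.shape)
        r_ab = superpose_kabsch(a, b).rmsd
        r_ba = superpose_kabsch(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        rot = Rotation.from_euler("zyx", [15, 75, -60], degrees=True).as_matrix()
        a2 = a @ rot.T + 11.0
        b2 = b @ rot.T + 11.0
        assert superpose_kabsch(a2, b2).rmsd == pytest.approx(r_ab, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_rotation_search(self, seed):
        # oracle: best r.m.s.d. over a large random sample of rotations with
        # centroid-matching translation; Kabsch must be at least as good and
        # the sample should come close to it
        a = _random_cloud(8, seed)
        b = _random_cloud(8, seed + 100)
        kabsch = superpose_kabsch(a, b).rmsd
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rots = Rotation.random(4000, random_state=seed).as_matrix()
        moved = np.einsum("rij,nj->rni", rots, ac)
        best = np.sqrt(np.mean(np.sum((moved - bc) ** 2, axis=2), axis=1).min())
        assert kabsch <= best + 1e-9
        assert best - kabsch < 0.15 * best + 0.05

    def test_rotation_always_proper_on_chiral_set(self):
        # a target that is the mirror image: optimal proper rotation must not
        # cheat with a reflection
        a = _random_cloud(8, 5)
        mirrored = a * np.array([1.0, 1.0, -1.0])
        res = superpose_kabsch(a, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1

    def test_degenerate_and_mismatched_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            superpose_kabsch(line, line + 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            superpose_kabsch(_random_cloud(5, 0), _random_cloud(6, 0))


def _backbone_chain(phi_psi: list[tuple[float, float]]) -> StructureModel:
    """Chain built residue by residue with prescribed φ/ψ (ideal geometry, NeRF)."""
    n_ca, ca_c, c_n = 1.458, 1.525, 1.329
    ang_n_ca_c, ang_ca_c_n, ang_c_n_ca = 111.0, 116.6, 121.9
    omega = 180.0

    def place(a, b, c, bond, angle, torsion):
        ab = b - a
        bc = c - b
        bc_n = bc / np.linalg.norm(bc)
        n_vec = np.cross(ab, bc)
        n_vec /= np.linalg.norm(n_vec)
        m = np.cross(n_vec, bc_n)
        ang, tor = np.radians(angle), np.radians(torsion)
        d2 = np.array(
            [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
        )
        return c + d2[0] * bc_n + d2[1] * m + d2[2] * n_vec

    atoms = [np.array([0.0, 0.0, 0.0]), np.array([n_ca, 0.0, 0.0])]
    atoms.append(place(np.array([0.0, 1.0, 0.0]), atoms[0], atoms[1], ca_c, ang_n_ca_c, 60.0))
    coords = [tuple(atoms)]  # residue 1: N, CA, C
    for phi, psi in phi_psi[1:]:
        prev_n, prev_ca, prev_c = coords[-1]
        # psi of previous residue sets its C->N bond placement
        prev_psi = phi_psi[len(coords) - 1][1]
        n = place(prev_n, prev_ca, prev_c, c_n, ang_ca_c_n, prev_psi)
        ca = place(prev_ca, prev_c, n, n_ca, ang_c_n_ca, omega)
        c = place(prev_c, n, ca, ca_c, ang_n_ca_c, phi)
        coords.append((n, ca, c))
    residues = [
        Residue(i + 1, "ALA", [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c)])
        for i, (n, ca, c) in enumerate(coords)
    ]
    return StructureModel(models=[[Chain("A", residues)]], id="helix")


class TestDihedrals:
    def test_four_point_formula_against_vector_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            p = rng.normal(0, 3, size=(4, 3))
            # independent oracle: signed angle between plane normals around b1
            b0, b1, b2 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
            cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            if np.dot(np.cross(n1, n2), b1) < 0:
                ang = -ang
            assert dihedral(*p) == pytest.approx(ang, abs=1e-6)

    def test_mirrored_coordinates_negate_dihedral(self):
        p = np.random.default_rng(4).normal(0, 2, size=(4, 3))
        d = dihedral(*p)
        pm = p * np.array([1.0, 1.0, -1.0])
        assert dihedral(*pm) == pytest.approx(-d, abs=1e-9) or (
            abs(d) == pytest.approx(180.0, abs=1e-9)
        )

    def test_ideal_helix_is_favored_general(self):
        model = _backbone_chain([(-57.0, -47.0)] * 8)
        points = dihedrals(model, "A")
        interior = [p for p in points if p.defined()]
        assert len(interior) == 6
        for p in interior:
            assert p.phi == pytest.approx(-57.0, abs=1.0)
            assert p.psi == pytest.approx(-47.0, abs=1.0)
            assert p.region == "favored-general"

    def test_terminal_residues_flagged_undefined(self):
        model = _backbone_chain([(-57.0, -47.0)] * 4)
        points = dihedrals(model, "A")
        assert points[0].phi is None
        assert points[-1].psi is None

    def test_positive_phi_extended_region_is_glycine_only(self):
        # the strained conformation the swap-prone mutant hinge adopts:
        # φ ≈ +120°, ψ ≈ ±150° — accessible to glycine, disallowed otherwise
        for psi in (150.0, -150.0):
            assert classify_rama(120.0, psi) == "glycine-only"
        assert classify_rama(-57.0, -47.0) == "favored-general"
        assert classify_rama(-120.0, 130.0) == "favored-general"
        assert classify_rama(60.0, 40.0) == "allowed-general"


def _metal_site(dist: float) -> StructureModel:
    metal = Residue(300, "CA", [Atom("CA", "CA", [0.0, 0.0, 0.0], is_hetero=True)])
    partner = Residue(10, "ASP", [
        Atom("CB", "C", [dist + 1.5, 0, 0]),
        Atom("OD1", "O", [dist, 0.0, 0.0]),
    ])
    return StructureModel(models=[[Chain("A", [partner, metal])]], id="site")


class TestCoordination:
    def test_ligand_exactly_beyond_cutoff_excluded(self):
        model = _metal_site(3.1)
        report = coordination_site(model, ("A", 300, "CA"), cutoff=3.0)
        assert report.ligands == []

    def test_ligand_within_cutoff_listed_with_distance(self):
        model = _metal_site(2.4)
        report = coordination_site(model, ("A", 300, "CA"), cutoff=3.0)
        assert len(report.ligands) == 1
        chain, resnum, resname, atom, d = report.ligands[0]
        assert (chain, resnum, resname, atom) == ("A", 10, "ASP", "OD1")
        assert d == pytest.approx(2.4, abs=1e-9)
        assert report.protein_ligands and not report.hetero_ligands

    def test_monotone_in_cutoff(self, toy_swap):
        dimer, _ = toy_swap
        metal = Residue(500, "CA", [Atom("CA", "CA", dimer.chains[0].residues[0].atoms[0].coords + 1.5, is_hetero=True)])
        chains = [Chain(dimer.chains[0].id, dimer.chains[0].residues + [metal]), dimer.chains[1]]
        model = StructureModel(models=[chains])
        small = coordination_site(model, ("A", 500, "CA"), cutoff=2.5)
        large = coordination_site(model, ("A", 500, "CA"), cutoff=4.0)
        small_set = {(l[0], l[1], l[3]) for l in small.ligands}
        large_set = {(l[0], l[1], l[3]) for l in large.ligands}
        assert small_set <= large_set

    def test_missing_metal_rejected(self, toy_swap):
        dimer, _ = toy_swap
        with pytest.raises(ValueError, match="not found"):
            coordination_site(dimer, ("A", 999, "ZN"))


def _traj_from(base: StructureModel, displacements: list[np.ndarray]) -> StructureModel:
    models = []
    for disp in displacements:
        i = 0
        chains = []
        for c in base.chains:
            residues = []
            for r in c.residues:
                atoms = []
                for a in r.atoms:
                    atoms.append(Atom(a.name, a.element, a.coords + disp[i]))
                    i += 1
                residues.append(Residue(r.number, r.name, atoms))
            chains.append(Chain(c.id, residues))
        models.append(chains)
    return StructureModel(models=models, id="traj")


class TestTrajectory:
    def test_identical_frames_all_zero(self, toy_swap):
        dimer, _ = toy_swap
        n_atoms = sum(len(r.atoms) for c in dimer.chains for r in c.residues)
        traj = _traj_from(dimer, [np.zeros((n_atoms, 3))] * 4)
        series = trajectory_rmsd(traj, Selection(atom_names=("CA",)))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_single_moved_atom_closed_form(self, toy_swap):
        dimer, _ = toy_swap
        n_atoms = sum(len(r.atoms) for c in dimer.chains for r in c.residues)
        disp = np.zeros((n_atoms, 3))
        refs = [(c.id, r.number, a.name) for c in dimer.chains for r in c.residues for a in r.atoms]
        ca_indices = [i for i, (_c, _n, name) in enumerate(refs) if name == "CA"]
        disp2 = disp.copy()
        disp2[ca_indices[0]] = [1.0, 0.0, 0.0]
        traj = _traj_from(dimer, [disp, disp2])
        series = trajectory_rmsd(traj, Selection(atom_names=("CA",)), superpose=False)
        n_ca = len(ca_indices)
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)
        assert series.values[1] == pytest.approx(1.0 / np.sqrt(n_ca), abs=1e-9)

    def test_gaussian_displacement_matches_expectation(self, toy_swap):
        dimer, _ = toy_swap
        n_atoms = sum(len(r.atoms) for c in dimer.chains for r in c.residues)
        sigma = 0.4
        rng = np.random.default_rng(17)
        disps = [np.zeros((n_atoms, 3))] + [
            rng.normal(0, sigma, size=(n_atoms, 3)) for _ in range(40)
        ]
        traj = _traj_from(dimer, disps)
        series = trajectory_rmsd(traj, Selection(), superpose=False)
        # E[rmsd²] = 3σ² for isotropic Gaussian displacements
        assert np.mean(series.values[1:] ** 2) == pytest.approx(3 * sigma**2, rel=0.1)

    def test_empty_selection_rejected(self, toy_swap):
        dimer, _ = toy_swap
        n_atoms = sum(len(r.atoms) for c in dimer.chains for r in c.residues)
        traj = _traj_from(dimer, [np.zeros((n_atoms, 3))] * 2)
        with pytest.raises(ValueError, match="no atoms"):
            trajectory_rmsd(traj, Selection(atom_names=("ZZ",)))
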