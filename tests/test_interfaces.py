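"""SASA against analytic oracles; interface areas and H-bond inventories."""

from __future__ import annotations

import numpy as np
import pytest

from gelswap.interfaces import (
    SasaParams,
    buried_area_open_minus_closed,
    complexation_surface,
    enumerate_hbonds,
    sasa,
    sphere_points,
)
from gelswap.structure import Atom, AtomRef, Chain, Residue, StructureModel


def _ref(name, element, pos, chain="A", resnum=1, resname="GLY"):
    return AtomRef(chain, resnum, "", resname, Atom(name, element, np.asarray(pos, float)))


PARAMS = SasaParams(n_points=960)
R_C = PARAMS.radius_of("C")
PROBE = PARAMS.probe


class TestSasaOracles:
    def test_isolated_atom_is_full_sphere(self):
        res = sasa([_ref("CA", "C", [0, 0, 0])], PARAMS)
        expected = 4 * np.pi * (R_C + PROBE) ** 2
        assert res.total == pytest.approx(expected, rel=1e-12)

    def test_two_distant_atoms_are_additive(self):
        r = R_C + PROBE
        refs = [_ref("CA", "C", [0, 0, 0]), _ref("CA", "C", [2 * r + 1.0, 0, 0], resnum=2)]
        res = sasa(refs, PARAMS)
        assert res.total == pytest.approx(2 * 4 * np.pi * r**2, rel=1e-12)

    @pytest.mark.parametrize("d", [1.5, 3.0, 4.5, 6.0])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        # analytic: buried cap on each sphere has height R - (d^2)/(2d) for
        # equal radii; accessible area = 4πR² − 2πR·h per sphere
        r = R_C + PROBE
        refs = [_ref("CA", "C", [0, 0, 0]), _ref("CA", "C", [d, 0, 0], resnum=2)]
        res = sasa(refs, SasaParams(n_points=2000))
        if d >= 2 * r:
            expected = 2 * 4 * np.pi * r**2
        else:
            x = d / 2.0  # plane of intersection for equal spheres
            cap_h = r - x
            expected = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * cap_h)
        assert res.total == pytest.approx(expected, rel=0.02)

    def test_unequal_radii_cap_oracle(self):
        d = 2.4
        refs = [_ref("CA", "C", [0, 0, 0]), _ref("N", "N", [d, 0, 0], resnum=2)]
        p = SasaParams(n_points=2000)
        r1 = p.radius_of("C") + p.probe
        r2 = p.radius_of("N") + p.probe
        x1 = (d**2 + r1**2 - r2**2) / (2 * d)
        x2 = d - x1
        expected = (4 * np.pi * r1**2 - 2 * np.pi * r1 * (r1 - x1)) + (
            4 * np.pi * r2**2 - 2 * np.pi * r2 * (r2 - x2)
        )
        assert sasa(refs, p).total == pytest.approx(expected, rel=0.02)

    def test_adding_atom_never_increases_others_area(self, toy_swap):
        from gelswap.structure import Selection, select

        dimer, _ = toy_swap
        refs = select(dimer, Selection(chains=("A",)))[:30]
        base = sasa(refs, SasaParams(n_points=500))
        extra = refs + [_ref("CA", "C", refs[0].atom.coords + 2.5, chain="X", resnum=999)]
        grown = sasa(extra, SasaParams(n_points=500))
        assert np.all(grown.per_atom[: len(refs)] <= base.per_atom + 1e-9)

    def test_lattice_refinement_converges(self, toy_swap):
        from gelswap.structure import Selection, select

        dimer, _ = toy_swap
        refs = select(dimer, Selection(chains=("A",)))
        a1 = sasa(refs, SasaParams(n_points=960)).total
        a2 = sasa(refs, SasaParams(n_points=1920)).total
        assert abs(a2 - a1) / a2 < 0.01

    def test_sphere_lattice_is_unit_and_uniformish(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        # centroid of a uniform spherical lattice is near the origin
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError, match="XX"):
            sasa([_ref("Q", "XX", [0, 0, 0])], PARAMS)


class TestInterfaceAreas:
    def test_identical_sets_bury_nothing(self, toy_swap):
        from gelswap.structure import Selection, select

        dimer, _ = toy_swap
        refs = select(dimer, Selection(chains=("A",)))
        assert buried_area_open_minus_closed(refs, refs, PARAMS) == pytest.approx(0.0, abs=1e-9)

    def test_extended_vs_compact_strand_positive_and_exact(self):
        # 10 single-atom residues: a straight strand vs the same atoms in a
        # hairpin; the difference must equal an independent recomputation
        line = [
            _ref("CA", "C", [3.8 * i, 0, 0], resnum=i + 1) for i in range(10)
        ]
        hairpin = [
            _ref("CA", "C", [3.8 * (i if i < 5 else 9 - i), 0 if i < 5 else 4.2, 0], resnum=i + 1)
            for i in range(10)
        ]
        p = SasaParams(n_points=960)
        diff = buried_area_open_minus_closed(line, hairpin, p)
        independent = sasa(line, p).total - sasa(hairpin, p).total
        assert diff > 0
        assert diff == pytest.approx(independent, abs=1e-9)

    def test_negative_buried_area_warns(self):
        lone = [_ref("CA", "C", [0, 0, 0])]
        pair = [_ref("CA", "C", [0, 0, 0]), _ref("CA", "C", [2.0, 0, 0], resnum=2)]
        with pytest.warns(UserWarning, match="negative buried area"):
            val = buried_area_open_minus_closed(lone, pair, PARAMS)
        assert val < 0

    def test_no_contact_complex_has_zero_surface(self):
        chains = [
            Chain("A", [Residue(1, "GLY", [Atom("CA", "C", [0.0, 0, 0])])]),
            Chain("B", [Residue(1, "GLY", [Atom("CA", "C", [50.0, 0, 0])])]),
        ]
        model = StructureModel(models=[chains])
        assert complexation_surface(model, "A", PARAMS) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_delta_sasa(self, toy_swap):
        from gelswap.structure import Selection, select

        dimer, _ = toy_swap
        p = SasaParams(n_points=500)
        val = complexation_surface(dimer, "A", p)
        # independent route: two full SASA runs assembled by hand
        all_refs = [r for r in select(dimer, Selection(include_water=False))
                    if r.atom.element != "H" and not r.atom.is_hetero]
        a_refs = [r for r in all_refs if r.chain_id == "A"]
        whole = sasa(all_refs, p)
        bound_a = sum(a for a, r in zip(whole.per_atom, whole.refs) if r.chain_id == "A")
        expected = sasa(a_refs, p).total - bound_a
        assert val == pytest.approx(expected, abs=1e-9)
        assert val > 0

    def test_unknown_chain_rejected(self, toy_swap):
        dimer, _ = toy_swap
        with pytest.raises(ValueError, match="'Q'"):
            complexation_surface(dimer, "Q", PARAMS)


def _strand_pair_model(n_rungs: int) -> StructureModel:
    """Idealized antiparallel ladder: per rung N(A)···O(B) and O(A)···N(B) at 2.9 Å."""
    res_a, res_b = [], []
    for i in range(n_rungs):
        x = 4.8 * i
        res_a.append(
            Residue(
                number=i + 1,
                name="ALA",
                atoms=[
                    Atom("N", "N", [x, 0.0, 0.0]),
                    Atom("CA", "C", [x + 1.2, -0.9, 0.0]),
                    Atom("C", "C", [x + 2.4, 0.0, 0.0]),
                    Atom("O", "O", [x + 2.4, 1.2, 0.0]),
                ],
            )
        )
        # partner strand: O below our N, N above our O
        res_b.append(
            Residue(
                number=i + 1,
                name="ALA",
                atoms=[
                    Atom("N", "N", [x + 2.4, 4.1, 0.0]),
                    Atom("CA", "C", [x + 1.2, 5.0, 0.0]),
                    Atom("C", "C", [x, 4.1, 0.0]),
                    Atom("O", "O", [x, 2.9, 0.0]),
                ],
            )
        )
    return StructureModel(
        models=[[Chain("A", res_a), Chain("B", res_b)]], id="ladder"
    )


class TestHBonds:
    def test_distant_residues_no_bonds(self):
        chains = [
            Chain("A", [Residue(1, "ALA", [Atom("N", "N", [0, 0, 0]), Atom("CA", "C", [1.4, 0, 0]), Atom("O", "O", [2.4, 0, 0])])]),
            Chain("B", [Residue(1, "ALA", [Atom("N", "N", [20, 0, 0]), Atom("CA", "C", [21.4, 0, 0]), Atom("O", "O", [22.4, 0, 0])])]),
        ]
        assert enumerate_hbonds(StructureModel(models=[chains])) == []

    @pytest.mark.parametrize("n_rungs", [2, 4, 6])
    def test_antiparallel_ladder_two_bonds_per_rung(self, n_rungs):
        model = _strand_pair_model(n_rungs)
        bonds = enumerate_hbonds(model, inter_chain_only=True)
        assert len(bonds) == 2 * n_rungs
        assert all(not b.is_salt_bridge for b in bonds)

    def test_salt_bridge_flagged_and_counted(self):
        # Arg guanidinium NH1 close to Glu carboxylate OE1
        arg = Residue(
            10,
            "ARG",
            atoms=[
                Atom("CZ", "C", [0.0, 0.0, 0.0]),
                Atom("NH1", "N", [1.3, 0.0, 0.0]),
            ],
        )
        glu = Residue(
            20,
            "GLU",
            atoms=[
                Atom("CD", "C", [5.6, 0.0, 0.0]),
                Atom("OE1", "O", [4.4, 0.0, 0.0]),
            ],
        )
        model = StructureModel(models=[[Chain("A", [arg]), Chain("B", [glu])]])
        bonds = enumerate_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].is_salt_bridge
        assert bonds[0].distance == pytest.approx(3.1, abs=1e-9)

    def test_charged_pair_beyond_hbond_within_salt_cutoff(self):
        # 3.8 Å: too long for an H-bond, inside the 4.0 Å salt-bridge window
        lys = Residue(5, "LYS", atoms=[Atom("CE", "C", [-1.4, 0, 0]), Atom("NZ", "N", [0.0, 0, 0])])
        asp = Residue(9, "ASP", atoms=[Atom("CG", "C", [5.2, 0, 0]), Atom("OD1", "O", [3.8, 0, 0])])
        model = StructureModel(models=[[Chain("A", [lys]), Chain("B", [asp])]])
        bonds = enumerate_hbonds(model)
        assert len(bonds) == 1 and bonds[0].is_salt_bridge

    def test_symmetric_under_chain_relabeling(self):
        model = _strand_pair_model(3)
        flipped_chains = [
            Chain(id={"A": "B", "B": "A"}[c.id], residues=c.residues) for c in model.chains
        ]
        flipped = StructureModel(models=[flipped_chains])
        assert len(enumerate_hbonds(model)) == len(enumerate_hbonds(flipped))

    def test_angle_criterion_rejects_blocked_donor(self):
        # acceptor sits behind the donor's antecedent (angle ~0°)
        donor_res = Residue(1, "ALA", atoms=[Atom("N", "N", [0, 0, 0]), Atom("CA", "C", [1.45, 0, 0])])
        acceptor_res = Residue(2, "ALA", atoms=[Atom("O", "O", [3.0, 0, 0]), Atom("C", "C", [4.2, 0, 0])])
        model = StructureModel(models=[[Chain("A", [donor_res]), Chain("B", [acceptor_res])]])
        assert enumerate_hbonds(model) == []

    def test_unknown_residue_warned_and_skipped(self):
        odd = Residue(1, "XYZ", atoms=[Atom("N1", "N", [0, 0, 0])])
        ok = Residue(1, "ALA", atoms=[Atom("N", "N", [3.0, 0, 0]), Atom("CA", "C", [4.45, 0, 0])])
        model = StructureModel(models=[[Chain("A", [odd]), Chain("B", [ok])]])
        with pytest.warns(UserWarning, match="unknown type"):
            bonds = enumerate_hbonds(model)
        assert bonds == []
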