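"""Superposition, backbone dihedrals, metal coordination and trajectory series.

Superposition uses the Kabsch algorithm (SVD of the cross-covariance with a
determinant correction, so the rotation is always proper — mirror solutions
are never returned).  Structure-to-structure correspondence is built from
author residue numbers over the intersection of modeled residues, minus any
user-supplied masks; this is the workflow behind masked Cα r.m.s.d. numbers
such as "0.40 Å over 79 Cα".

Ramachandran classification is intentionally coarse: rectangular favored /
allowed regions for general residues plus the extended positive-φ region
that only glycine can occupy.  That is enough to make qualitative calls like
"this φ/ψ pair is accessible only to glycine" — the scientific claim the
classification exists to support — without pretending to a contour accuracy
no published map would license at this granularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import json

import numpy as np

from .structure import Chain, Selection, StructureModel, coords_of, iter_atoms, select

__all__ = [
    "SuperpositionResult",
    "RamaPoint",
    "CoordinationReport",
    "TrajectorySeries",
    "superpose_kabsch",
    "pair_ca_by_number",
    "dihedral",
    "dihedrals",
    "classify_rama",
    "coordination_site",
    "trajectory_rmsd",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int
    selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "rmsd": self.rmsd,
                "n_atoms": self.n_atoms,
                "selection": self.selection,
            },
            indent=2,
        )


def superpose_kabsch(
    mobile: np.ndarray, target: np.ndarray, selection: str = ""
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Inputs are (n, 3) arrays in 1:1 correspondence, n ≥ 3.  Returns the
    proper rotation R and translation t minimising ‖(mobile·Rᵀ + t) − target‖
    and the post-fit r.m.s.d.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"length mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    # degenerate (e.g. collinear) sets leave the rotation underdetermined
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate point set: superposition underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    trans = tc - mc @ rot.T
    return SuperpositionResult(
        rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(mobile), selection=selection
    )


def pair_ca_by_number(
    model_a: StructureModel,
    chain_a: str,
    model_b: StructureModel,
    chain_b: str,
    exclude_ranges: Sequence[tuple[int, int]] = (),
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Paired Cα coordinates over the intersection of author residue numbers.

    ``exclude_ranges`` (inclusive) masks residues out of the correspondence —
    e.g. a flexible hinge loop and a disordered C-terminal stretch.
    Returns (coords_a, coords_b, residue_numbers).
    """
    def ca_map(model: StructureModel, cid: str) -> dict[int, np.ndarray]:
        chain = model.chain(cid)
        if chain is None:
            raise ValueError(f"chain {cid!r} not found")
        out = {}
        for res in chain.residues:
            if not res.is_amino_acid or res.insertion_code:
                continue
            ca = res.atom("CA")
            if ca is not None:
                out[res.number] = ca.coords
        return out

    ca_a = ca_map(model_a, chain_a)
    ca_b = ca_map(model_b, chain_b)
    common = sorted(set(ca_a) & set(ca_b))
    kept = [
        n for n in common if not any(lo <= n <= hi for lo, hi in exclude_ranges)
    ]
    if not kept:
        raise ValueError("no residues left after masking")
    return (
        np.array([ca_a[n] for n in kept]),
        np.array([ca_b[n] for n in kept]),
        kept,
    )


# ---------------------------------------------------------------------------
# Dihedrals / Ramachandran
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    # negated atan2 gives the IUPAC sign convention (matches Bio.PDB)
    ang = float(-np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


# Coarse rectangular Ramachandran regions, (phi_lo, phi_hi, psi_lo, psi_hi).
# psi ranges may wrap past +180 (expressed by hi > 180, tested modulo 360).
_FAVORED_GENERAL = [
    (-160.0, -45.0, -70.0, -5.0),    # right-handed alpha
    (-180.0, -90.0, 100.0, 200.0),   # beta (psi wraps through 180)
]
_ALLOWED_GENERAL = [
    (-180.0, -20.0, -110.0, 60.0),   # broad alpha basin
    (-180.0, -45.0, 60.0, 220.0),    # broad beta / PPII basin (wraps)
    (20.0, 100.0, -30.0, 90.0),      # left-handed helix
]
# Positive-phi extended strip essentially exclusive to glycine
_GLYCINE_ONLY = [
    (45.0, 180.0, 110.0, 250.0),     # includes psi ~ ±150 via wrap
    (45.0, 180.0, -180.0, -110.0),
]


def _in_region(phi: float, psi: float, boxes: list[tuple[float, float, float, float]]) -> bool:
    for plo, phi_hi, slo, shi in boxes:
        if plo <= phi <= phi_hi:
            if slo <= psi <= shi or slo <= psi + 360.0 <= shi:
                return True
    return False


def classify_rama(phi: float, psi: float, residue_name: str = "ALA") -> str:
    """Region label for a φ/ψ pair: favored/allowed general, glycine-only, disallowed."""
    if _in_region(phi, psi, _FAVORED_GENERAL):
        return "favored-general"
    if _in_region(phi, psi, _ALLOWED_GENERAL):
        return "allowed-general"
    if _in_region(phi, psi, _GLYCINE_ONLY):
        return "glycine-only"
    return "disallowed"


@dataclass
class RamaPoint:
    chain_id: str
    res_number: int
    res_name: str
    phi: float | None  # None at chain termini / missing backbone
    psi: float | None
    region: str | None

    def defined(self) -> bool:
        return self.phi is not None and self.psi is not None


def dihedrals(model: StructureModel, chain: str, model_index: int = 0) -> list[RamaPoint]:
    """Backbone φ/ψ and Ramachandran region per residue of one chain.

    φ needs the previous residue's C, ψ the next residue's N; terminal or
    incompletely modeled residues are flagged undefined rather than raising.
    A gap in author numbering (missing loop) also breaks the neighbour link.
    """
    ch = model.chain(chain, model=model_index)
    if ch is None:
        raise ValueError(f"chain {chain!r} not found")
    residues = sorted(
        (r for r in ch.residues if r.is_amino_acid), key=lambda r: (r.number, r.insertion_code)
    )
    points: list[RamaPoint] = []
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 and residues[i - 1].number == res.number - 1 else None
        next_res = (
            residues[i + 1]
            if i + 1 < len(residues) and residues[i + 1].number == res.number + 1
            else None
        )
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if prev_res is not None and prev_res.atom("C") is not None:
                phi = dihedral(prev_res.atom("C").coords, n.coords, ca.coords, c.coords)
            if next_res is not None and next_res.atom("N") is not None:
                psi = dihedral(n.coords, ca.coords, c.coords, next_res.atom("N").coords)
        region = classify_rama(phi, psi, res.name) if phi is not None and psi is not None else None
        points.append(RamaPoint(ch.id, res.number, res.name, phi, psi, region))
    return points


def write_dihedral_table(points: list[RamaPoint], path) -> None:
    from pathlib import Path

    lines = ["chain\tresidue\tresname\tphi\tpsi\tregion"]
    for p in points:
        phi = f"{p.phi:.1f}" if p.phi is not None else "NA"
        psi = f"{p.psi:.1f}" if p.psi is not None else "NA"
        lines.append(f"{p.chain_id}\t{p.res_number}\t{p.res_name}\t{phi}\t{psi}\t{p.region or 'NA'}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Metal coordination
# ---------------------------------------------------------------------------

@dataclass
class CoordinationReport:
    metal: tuple[str, int, str, str]  # chain, residue number, residue name, atom name
    ligands: list[tuple[str, int, str, str, float]]  # chain, resnum, resname, atom, distance
    cutoff: float

    @property
    def chelating_residues(self) -> list[tuple[str, int, str]]:
        seen = []
        for c, n, rn, _a, _d in self.ligands:
            if (c, n, rn) not in seen:
                seen.append((c, n, rn))
        return seen

    @property
    def protein_ligands(self) -> list[tuple[str, int, str, str, float]]:
        from .structure import _STANDARD_AA

        return [l for l in self.ligands if l[2] in _STANDARD_AA]

    @property
    def hetero_ligands(self) -> list[tuple[str, int, str, str, float]]:
        from .structure import _STANDARD_AA

        return [l for l in self.ligands if l[2] not in _STANDARD_AA]


def coordination_site(
    model: StructureModel,
    metal: tuple[str, int, str],
    cutoff: float = 3.0,
    include_water: bool = False,
) -> CoordinationReport:
    """O/N atoms within ``cutoff`` of a metal atom (chain, residue number, atom name).

    Distances are strict (≤ cutoff); an empty ligand list is a valid result,
    not an error — it simply means nothing coordinates at that radius.
    """
    chain_id, res_number, atom_name = metal
    metal_ref = None
    for ref in iter_atoms(model):
        if (
            ref.chain_id == chain_id
            and ref.res_number == res_number
            and ref.atom.name == atom_name
        ):
            metal_ref = ref
            break
    if metal_ref is None:
        raise ValueError(f"metal atom {metal} not found")
    ligands = []
    for ref in iter_atoms(model):
        if ref is metal_ref or ref.res_key == metal_ref.res_key:
            continue
        if ref.atom.element not in ("O", "N"):
            continue
        if not include_water and ref.res_name in ("HOH", "WAT", "DOD"):
            continue
        d = float(np.linalg.norm(ref.atom.coords - metal_ref.atom.coords))
        if d <= cutoff:
            ligands.append((ref.chain_id, ref.res_number, ref.res_name, ref.atom.name, d))
    ligands.sort(key=lambda t: t[4])
    return CoordinationReport(
        metal=(chain_id, res_number, metal_ref.res_name, atom_name),
        ligands=ligands,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Multi-model (trajectory) series
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySeries:
    metric: str
    values: np.ndarray
    model_indices: list[int]


def trajectory_rmsd(
    traj: StructureModel,
    selection: Selection,
    reference: int = 0,
    superpose: bool = True,
) -> TrajectorySeries:
    """Per-model r.m.s.d. of a selection against a reference model.

    Frames are rigid-body superposed onto the reference before the r.m.s.d.
    by default (the molecular-dynamics convention); pass ``superpose=False``
    for raw coordinate deviations.
    """
    if traj.n_models < 2:
        raise ValueError("trajectory r.m.s.d. needs at least 2 models")
    ref_refs = select(traj, selection, model_index=reference)
    if not ref_refs:
        raise ValueError("selection matches no atoms")
    ref_xyz = coords_of(ref_refs)
    values = []
    for m in range(traj.n_models):
        refs_m = select(traj, selection, model_index=m)
        if len(refs_m) != len(ref_refs):
            raise ValueError(f"model {m}: selection size differs from reference")
        xyz = coords_of(refs_m)
        if superpose:
            values.append(superpose_kabsch(xyz, ref_xyz).rmsd)
        else:
            values.append(float(np.sqrt(np.mean(np.sum((xyz - ref_xyz) ** 2, axis=1)))))
    return TrajectorySeries(
        metric=f"ca_rmsd_vs_model_{reference}",
        values=np.array(values),
        model_indices=list(range(traj.n_models)),
    )
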