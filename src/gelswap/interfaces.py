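"""Solvent-accessible surface areas and protein–protein interface metrics.

SASA is computed with the Shrake–Rupley rolling-probe method on a
*deterministic* golden-spiral sphere lattice: for each atom, test points on
a sphere of radius (r_atom + probe) are marked buried if they fall inside
any neighbour's probe-expanded sphere; the accessible area is the surviving
point fraction times the full sphere area.  Determinism matters because the
buried-area and complexation-surface numbers feed table-level comparisons.

Two interface areas are reported per subunit, following the conventions
used for domain-swapped assemblies:

* buried interaction area = SASA(open monomer) − SASA(closed monomer),
  both isolated — the area the swap-extended conformation exposes;
* total interaction surface = SASA(subunit isolated) − SASA(subunit in the
  complex) — the classical ΔSASA on complexation (PISA-style).

Hydrogen bonds are enumerated heavy-atom-only (N/O donors to N/O
acceptors) with a donor-antecedent angle criterion replacing the missing
hydrogen, and salt bridges are flagged between oppositely charged groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRef, Selection, StructureModel, iter_atoms, select

__all__ = [
    "SasaParams",
    "SasaResult",
    "InterfaceReport",
    "HBond",
    "sasa",
    "buried_area_open_minus_closed",
    "complexation_surface",
    "enumerate_hbonds",
    "sphere_points",
    "VDW_RADII",
]

#: NACCESS-flavoured heavy-atom van der Waals radii (Å), element-keyed.
#: Configurable: pass a modified mapping through SasaParams.radii.
VDW_RADII: dict[str, float] = {
    "C": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "D": 1.00,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "CA": 1.74,  # calcium ion
    "MG": 1.60,
    "ZN": 1.39,
    "NA": 1.80,
    "K": 2.20,
}


@dataclass(frozen=True)
class SasaParams:
    probe: float = 1.4  # water-probe radius, Å
    n_points: int = 960  # sphere lattice size; error scales ~ 1/sqrt(n)
    radii: dict[str, float] | None = None  # overrides element defaults
    radii_name: str = "naccess-like"

    def radius_of(self, element: str) -> float:
        table = dict(VDW_RADII)
        if self.radii:
            table.update({k.upper(): v for k, v in self.radii.items()})
        el = element.upper()
        if el not in table:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        return table[el]


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Å², aligned with the input atom order
    refs: list[AtomRef]
    params: SasaParams

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def per_residue(self) -> dict[tuple[str, int, str], float]:
        out: dict[tuple[str, int, str], float] = {}
        for area, ref in zip(self.per_atom, self.refs):
            out[ref.res_key] = out.get(ref.res_key, 0.0) + float(area)
        return out


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral), (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(atoms: Sequence[AtomRef], params: SasaParams | None = None) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area of an atom list.

    Waters should be excluded by the caller when a protein-only surface is
    wanted; the routine itself treats every atom it is given as part of the
    body.
    """
    params = params or SasaParams()
    if params.probe <= 0:
        raise ValueError("probe radius must be positive")
    if params.n_points < 100:
        raise ValueError("n_points must be at least 100 for a usable lattice")
    refs = list(atoms)
    if not refs:
        raise ValueError("empty atom list")
    radii = np.array([params.radius_of(r.atom.element) for r in refs])
    xyz = np.array([r.atom.coords for r in refs])
    expanded = radii + params.probe
    lattice = sphere_points(params.n_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(refs))
    for i in range(len(refs)):
        ri = expanded[i]
        pts = xyz[i] + ri * lattice
        neighbors = [j for j in tree.query_ball_point(xyz[i], ri + expanded.max()) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * ri**2
    return SasaResult(per_atom=areas, refs=refs, params=params)


def _protein_atoms(model: StructureModel, chain: str | None = None) -> list[AtomRef]:
    sel = Selection(chains=(chain,) if chain else None, include_water=False)
    return [r for r in select(model, sel) if r.atom.element != "H"]


def buried_area_open_minus_closed(
    open_atoms: Sequence[AtomRef],
    closed_atoms: Sequence[AtomRef],
    params: SasaParams | None = None,
) -> float:
    """Per-subunit buried interaction area: SASA(open) − SASA(closed), isolated.

    A negative value is returned as-is with a warning — it means the
    nominally open form is not actually more exposed than the closed one.
    """
    params = params or SasaParams()
    if not open_atoms or not closed_atoms:
        raise ValueError("both atom sets must be non-empty")
    area = sasa(open_atoms, params).total - sasa(closed_atoms, params).total
    if area < 0:
        warnings.warn("open form is less exposed than closed form (negative buried area)")
    return area


def complexation_surface(
    complex_model: StructureModel,
    subunit: str,
    params: SasaParams | None = None,
    include_hetero: bool = False,
) -> float:
    """Per-subunit ΔSASA on complexation: SASA(chain isolated) − SASA(chain in complex)."""
    params = params or SasaParams()
    chains = {c.id for c in complex_model.chains}
    if subunit not in chains:
        raise ValueError(f"chain {subunit!r} not in complex (has {sorted(chains)})")
    if len(chains) < 2:
        raise ValueError("complexation surface requires at least 2 chains")
    all_atoms = [
        r
        for r in _protein_atoms(complex_model)
        if include_hetero or not r.atom.is_hetero
    ]
    sub_atoms = [r for r in all_atoms if r.chain_id == subunit]
    if not sub_atoms:
        raise ValueError(f"chain {subunit!r} has no atoms after filtering")
    in_complex = sasa(all_atoms, params)
    bound = sum(
        a for a, ref in zip(in_complex.per_atom, in_complex.refs) if ref.chain_id == subunit
    )
    isolated = sasa(sub_atoms, params).total
    return float(isolated - bound)


# ---------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

# Side-chain donor / acceptor heavy atoms per residue type.  Backbone N is a
# donor (except proline) and backbone O / OXT are acceptors for all residues.
_SC_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
_SC_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": set(),
    # citrate from the crystallisation buffer: all oxygens accept
    "CIT": {"O1", "O2", "O3", "O4", "O5", "O6", "O7"},
    "FLC": {"O1", "O2", "O3", "O4", "O5", "O6", "O7"},
}
# Charged groups for salt-bridge flagging.
_POS_CHARGED: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_NEG_CHARGED: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "CIT": {"O1", "O2", "O3", "O4", "O5", "O6", "O7"},
    "FLC": {"O1", "O2", "O3", "O4", "O5", "O6", "O7"},
}

_KNOWN_RESIDUES = (
    set(_SC_DONORS)
    | set(_SC_ACCEPTORS)
    | {
        "ALA", "CYS", "GLY", "ILE", "LEU", "PHE", "PRO", "VAL",
        "HOH", "WAT", "CA", "MG", "ZN", "NA", "CL",
    }
)


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    is_salt_bridge: bool

    def as_row(self) -> tuple:
        d, a = self.donor, self.acceptor
        return (
            d.chain_id, d.res_number, d.res_name, d.atom.name,
            a.chain_id, a.res_number, a.res_name, a.atom.name,
            round(self.distance, 2),
            "salt_bridge" if self.is_salt_bridge else "hbond",
        )


@dataclass
class InterfaceReport:
    """Table-style summary of a two-chain interface."""

    buried_area_per_subunit: float | None = None
    total_interaction_surface_per_subunit: float | None = None
    hbonds: list[HBond] = field(default_factory=list)

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)

    @property
    def n_salt_bridges(self) -> int:
        return sum(1 for h in self.hbonds if h.is_salt_bridge)

    def to_json(self) -> str:
        return json.dumps(
            {
                "buried_area_per_subunit_A2": self.buried_area_per_subunit,
                "total_interaction_surface_per_subunit_A2": self.total_interaction_surface_per_subunit,
                "n_intermolecular_hbonds": self.n_hbonds,
                "n_salt_bridges": self.n_salt_bridges,
                "hbonds": [h.as_row() for h in self.hbonds],
            },
            indent=2,
        )

    def write_contacts_tsv(self, path: str | Path) -> None:
        header = "chainA\tresA\tresnameA\tatomA\tchainB\tresB\tresnameB\tatomB\tdistance\ttype"
        rows = ["\t".join(str(x) for x in h.as_row()) for h in self.hbonds]
        Path(path).write_text("\n".join([header, *rows]) + "\n")


def _donor_acceptor_roles(ref: AtomRef) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for a heavy atom, by residue/atom name."""
    res, name = ref.res_name, ref.atom.name
    el = ref.atom.element
    donor = False
    acceptor = False
    if el in ("N", "O"):
        if name == "N" and res != "PRO":
            donor = True
        if name in ("O", "OXT"):
            acceptor = True
        if name in _SC_DONORS.get(res, ()):  # side chains
            donor = True
        if name in _SC_ACCEPTORS.get(res, ()):
            acceptor = True
    return donor, acceptor


def _is_charged_pair(d: AtomRef, a: AtomRef) -> bool:
    d_pos = d.atom.name in _POS_CHARGED.get(d.res_name, ())
    a_neg = a.atom.name in _NEG_CHARGED.get(a.res_name, ()) or a.atom.name == "OXT"
    return d_pos and a_neg


def enumerate_hbonds(
    complex_model: StructureModel,
    inter_chain_only: bool = True,
    d_max: float = 3.5,
    angle_min: float = 90.0,
    salt_bridge_cutoff: float = 4.0,
    include_hetero: bool = True,
) -> list[HBond]:
    """Heavy-atom hydrogen-bond and salt-bridge inventory.

    A pair qualifies as an H-bond when an N/O donor lies within ``d_max`` of
    an N/O acceptor and the antecedent–donor–acceptor angle is at least
    ``angle_min`` degrees (the antecedent is the nearest covalently bonded
    heavy atom, standing in for the unresolved hydrogen).  Charged pairs
    (Arg/Lys/His vs Asp/Glu/C-terminus/citrate) within
    ``salt_bridge_cutoff`` are included and flagged as salt bridges even
    when they miss the tighter H-bond distance.
    """
    refs = [
        r
        for r in iter_atoms(complex_model)
        if r.atom.element != "H"
        and r.res_name not in ("HOH", "WAT", "DOD")
        and (include_hetero or not r.atom.is_hetero)
    ]
    unknown = sorted(
        {r.res_name for r in refs if r.res_name not in _KNOWN_RESIDUES}
    )
    if unknown:
        warnings.warn(f"skipping residues of unknown type: {unknown}")
        refs = [r for r in refs if r.res_name not in unknown]
    if not refs:
        return []
    xyz = np.array([r.atom.coords for r in refs])
    tree = cKDTree(xyz)

    # antecedent: nearest same-residue heavy atom within covalent range
    def antecedent(i: int) -> np.ndarray | None:
        best, best_d = None, np.inf
        for j in tree.query_ball_point(xyz[i], 2.0):
            if j == i or refs[j].res_key != refs[i].res_key:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d < best_d:
                best, best_d = xyz[j], d
        return best

    reach = max(d_max, salt_bridge_cutoff)
    bonds: list[HBond] = []
    for i, j in sorted(map(tuple, tree.query_pairs(reach, output_type="ndarray"))):
        a, b = refs[i], refs[j]
        if a.res_key == b.res_key:
            continue
        if inter_chain_only and a.chain_id == b.chain_id:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        for di, ai in ((i, j), (j, i)):
            dref, aref = refs[di], refs[ai]
            is_donor, _ = _donor_acceptor_roles(dref)
            _, is_acceptor = _donor_acceptor_roles(aref)
            if not (is_donor and is_acceptor):
                continue
            charged = _is_charged_pair(dref, aref)
            if d > d_max and not (charged and d <= salt_bridge_cutoff):
                continue
            ante = antecedent(di)
            if ante is not None:
                v1 = ante - xyz[di]
                v2 = xyz[ai] - xyz[di]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < angle_min:
                    continue
            bonds.append(HBond(donor=dref, acceptor=aref, distance=d, is_salt_bridge=charged))
            break  # count each heavy-atom pair once
    return bonds
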