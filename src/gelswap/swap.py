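"""Detection and bookkeeping of 3D domain swapping in two-chain assemblies.

A domain-swapped dimer is recognised from its contact topology alone: a
terminal segment of each chain packs against the *partner* chain's core
(inter-chain contacts dominate), while the core packs against itself.  The
connector between the exchanged segment and the core — the hinge loop — is
the stretch whose contacts are mixed or absent.  Interfaces are classified
with the open/closed-monomer (O/C) nomenclature: a contact reconstituting
the closed monomer's internal interface (i.e. involving a swapped segment or
hinge) is O-interface; a genuinely new contact between the two closed
subunits is C-interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    AtomRef,
    Chain,
    Residue,
    Selection,
    StructureModel,
    iter_atoms,
)

__all__ = [
    "ContactMap",
    "SwapAssignment",
    "InterfaceClassification",
    "contact_map",
    "detect_swap",
    "classify_interfaces",
    "reconstruct_monomers",
    "write_label_table",
]

#: heavy-atom minimal-distance cutoff defining a residue contact (Å)
DEFAULT_CONTACT_CUTOFF = 4.5
#: shortest terminal run accepted as a swapped segment (residues)
DEFAULT_MIN_SEGMENT = 4
#: sequence separation below which intra-chain contacts are ignored as local
LOCAL_SEQ_SEPARATION = 2

ResKey = tuple[str, int, str]  # (chain id, author number, insertion code)


@dataclass
class ContactMap:
    """Minimal heavy-atom distances for all residue pairs within a cutoff."""

    distances: dict[tuple[ResKey, ResKey], float]
    cutoff: float

    def __post_init__(self) -> None:
        # store each undirected pair once, under sorted key order
        canon: dict[tuple[ResKey, ResKey], float] = {}
        for (a, b), d in self.distances.items():
            key = (a, b) if a <= b else (b, a)
            canon[key] = min(d, canon.get(key, np.inf))
        self.distances = canon

    def pairs(self) -> list[tuple[ResKey, ResKey, float]]:
        return [(a, b, d) for (a, b), d in sorted(self.distances.items())]

    def inter_chain_pairs(self) -> list[tuple[ResKey, ResKey, float]]:
        return [(a, b, d) for a, b, d in self.pairs() if a[0] != b[0]]

    def contacts_of(self, key: ResKey) -> list[tuple[ResKey, float]]:
        out = []
        for (a, b), d in self.distances.items():
            if a == key:
                out.append((b, d))
            elif b == key:
                out.append((a, d))
        return sorted(out)


@dataclass
class SwapAssignment:
    """Per-chain swapped segment / hinge ranges and per-residue labels."""

    is_swapped: bool
    swapped_segment: dict[str, tuple[int, int] | None]
    hinge: dict[str, tuple[int, int] | None]
    labels: dict[ResKey, str]  # 'swapped' | 'hinge' | 'core'
    contact_counts: dict[ResKey, tuple[int, int]] = field(default_factory=dict)  # (inter, intra)

    def n_swapped(self, chain_id: str) -> int:
        seg = self.swapped_segment.get(chain_id)
        return 0 if seg is None else seg[1] - seg[0] + 1

    def n_hinge(self, chain_id: str) -> int:
        rng = self.hinge.get(chain_id)
        return 0 if rng is None else rng[1] - rng[0] + 1

    def label_of(self, chain_id: str, number: int, icode: str = "") -> str | None:
        return self.labels.get((chain_id, number, icode))

    def to_json(self) -> str:
        payload = {
            "is_swapped": self.is_swapped,
            "swapped_segment": {c: list(s) if s else None for c, s in self.swapped_segment.items()},
            "hinge": {c: list(h) if h else None for c, h in self.hinge.items()},
            "labels": [
                {"chain": c, "residue": n, "insertion_code": i, "label": lab}
                for (c, n, i), lab in sorted(self.labels.items())
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass
class InterfaceClassification:
    """Inter-chain residue contacts labeled O-interface or C-interface."""

    o_contacts: list[tuple[ResKey, ResKey, float]]
    c_contacts: list[tuple[ResKey, ResKey, float]]

    @property
    def n_o(self) -> int:
        return len(self.o_contacts)

    @property
    def n_c(self) -> int:
        return len(self.c_contacts)


def contact_map(
    model: StructureModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_hetero: bool = False,
    model_index: int = 0,
) -> ContactMap:
    """All residue pairs whose minimal heavy-atom distance is ≤ ``cutoff``.

    Hydrogens are ignored (crystal structures rarely carry them); waters and
    other heteroatoms are excluded unless ``include_hetero``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    refs = [
        r
        for r in iter_atoms(model, model_index)
        if r.atom.element != "H"
        and r.res_name not in ("HOH", "WAT", "DOD")
        and (include_hetero or not r.atom.is_hetero)
    ]
    if not refs:
        raise ValueError("empty model: no heavy atoms to build a contact map from")
    xyz = np.array([r.atom.coords for r in refs])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    distances: dict[tuple[ResKey, ResKey], float] = {}
    for i, j in pairs:
        ki, kj = refs[i].res_key, refs[j].res_key
        if ki == kj:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        key = (ki, kj) if ki <= kj else (kj, ki)
        if d < distances.get(key, np.inf):
            distances[key] = d
    return ContactMap(distances=distances, cutoff=cutoff)


def _residue_scores(
    cmap: ContactMap, chains: list[Chain]
) -> dict[ResKey, tuple[int, int]]:
    """Per residue: (# inter-chain contacts, # non-local intra-chain contacts)."""
    counts: dict[ResKey, tuple[int, int]] = {
        (c.id, r.number, r.insertion_code): (0, 0) for c in chains for r in c.residues
    }
    for a, b, _d in cmap.pairs():
        if a not in counts or b not in counts:
            continue
        if a[0] != b[0]:
            for k in (a, b):
                inter, intra = counts[k]
                counts[k] = (inter + 1, intra)
        else:
            if abs(a[1] - b[1]) <= LOCAL_SEQ_SEPARATION:
                continue  # sequence neighbours carry no packing signal
            for k in (a, b):
                inter, intra = counts[k]
                counts[k] = (inter, intra + 1)
    return counts


def _terminal_run(
    residues: list[Residue],
    chain_id: str,
    counts: dict[ResKey, tuple[int, int]],
    min_segment: int,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None, bool]:
    """Find a swapped run + hinge starting from one terminus.

    Returns (segment range, hinge range, from_n_terminus).  Residues are
    scored inter-dominant (score > 0), intra-dominant (score < 0) or
    ambiguous (tie / contactless; absorbed into the terminal segment when
    they dangle outside the core, otherwise they seed the hinge).
    """
    ordered = sorted(residues, key=lambda r: (r.number, r.insertion_code))

    def score(r: Residue) -> int:
        inter, intra = counts[(chain_id, r.number, r.insertion_code)]
        return inter - intra

    for seq in (ordered, ordered[::-1]):
        n = len(seq)
        i = 0
        # ambiguous residues at the very terminus dangle outside the core
        while i < n and score(seq[i]) == 0:
            i += 1
        j = i
        while j < n and score(seq[j]) > 0:
            j += 1
        n_inter = j - i
        if n_inter >= min_segment:
            seg_members = seq[0:j]
            h = j
            while h < n and score(seq[h]) == 0:
                h += 1
            hinge_members = seq[j:h]
            seg_nums = sorted(r.number for r in seg_members)
            seg = (seg_nums[0], seg_nums[-1])
            if hinge_members:
                h_nums = sorted(r.number for r in hinge_members)
                hinge = (h_nums[0], h_nums[-1])
            else:
                hinge = None
            return seg, hinge, seq is ordered
    return None, None, True


def detect_swap(
    dimer: StructureModel,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> SwapAssignment:
    """Identify reciprocally exchanged terminal segments in a two-chain assembly.

    Each residue is scored by (inter-chain contacts) − (non-local intra-chain
    contacts).  A terminal run of inter-dominant residues of length ≥
    ``min_segment`` is a swapped segment; the ambiguous stretch between it
    and the first intra-dominant (core) residue is the hinge.  The assembly
    is swapped only when *both* chains donate such a segment.
    """
    chains = dimer.polymer_chains()
    if len(chains) > 2:
        raise ValueError(
            f"{len(chains)} polymer chains present; pre-select a chain pair before swap detection"
        )
    if len(chains) != 2:
        raise ValueError("swap detection requires exactly 2 polypeptide chains")
    if not any(c.residues for c in chains):
        raise ValueError("no modeled residues")

    cmap = contact_map(dimer, cutoff=cutoff)
    counts = _residue_scores(cmap, chains)

    segments: dict[str, tuple[int, int] | None] = {}
    hinges: dict[str, tuple[int, int] | None] = {}
    for chain in chains:
        protein = [r for r in chain.residues if r.is_amino_acid]
        seg, hinge, _from_n = _terminal_run(protein, chain.id, counts, min_segment)
        segments[chain.id] = seg
        hinges[chain.id] = hinge

    is_swapped = all(segments[c.id] is not None for c in chains)

    labels: dict[ResKey, str] = {}
    for chain in chains:
        seg = segments[chain.id]
        hinge = hinges[chain.id]
        for r in chain.residues:
            if not r.is_amino_acid:
                continue
            key = (chain.id, r.number, r.insertion_code)
            if is_swapped and seg and seg[0] <= r.number <= seg[1]:
                labels[key] = "swapped"
            elif is_swapped and hinge and hinge[0] <= r.number <= hinge[1]:
                labels[key] = "hinge"
            else:
                labels[key] = "core"

    if not is_swapped:
        segments = {c.id: None for c in chains}
        hinges = {c.id: None for c in chains}

    return SwapAssignment(
        is_swapped=is_swapped,
        swapped_segment=segments,
        hinge=hinges,
        labels=labels,
        contact_counts=counts,
    )


def classify_interfaces(
    dimer: StructureModel,
    swap: SwapAssignment,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> InterfaceClassification:
    """Label every inter-chain residue contact O-interface or C-interface.

    O-interface: at least one member of the pair lies in a swapped segment
    or hinge, i.e. the contact recreates the closed monomer's internal
    packing across chains.  C-interface: both members are core residues —
    a contact the closed subunits make that the monomer never had.
    """
    if not swap.is_swapped:
        raise ValueError("interface classification requires a swapped assembly")
    cmap = contact_map(dimer, cutoff=cutoff)
    o_list, c_list = [], []
    for a, b, d in cmap.inter_chain_pairs():
        la = swap.labels.get(a, "core")
        lb = swap.labels.get(b, "core")
        if la in ("swapped", "hinge") or lb in ("swapped", "hinge"):
            o_list.append((a, b, d))
        else:
            c_list.append((a, b, d))
    return InterfaceClassification(o_contacts=o_list, c_contacts=c_list)


def reconstruct_monomers(
    dimer: StructureModel, swap: SwapAssignment
) -> dict[str, tuple[StructureModel, StructureModel]]:
    """Open monomer and closed composite for each subunit, in dimer coordinates.

    The *open monomer* of a subunit is its full polypeptide chain (core plus
    the segment it donates, in the extended conformation).  The *closed
    composite* is that chain's core + hinge plus the *partner's* donated
    segment — the monomer-equivalent folded unit.
    """
    if not swap.is_swapped:
        raise ValueError("monomer reconstruction requires a swapped assembly")
    chains = dimer.polymer_chains()
    if len(chains) != 2:
        raise ValueError("expected exactly 2 polypeptide chains")
    by_id = {c.id: c for c in chains}
    partner = {chains[0].id: chains[1].id, chains[1].id: chains[0].id}

    out: dict[str, tuple[StructureModel, StructureModel]] = {}
    for cid, chain in by_id.items():
        open_model = StructureModel(
            models=[[Chain(id=cid, residues=list(chain.residues))]],
            id=f"{dimer.id}:{cid}:open",
        )
        seg_self = swap.swapped_segment[cid]
        pid = partner[cid]
        seg_partner = swap.swapped_segment[pid]
        core_res = [
            r
            for r in chain.residues
            if r.is_amino_acid and not (seg_self and seg_self[0] <= r.number <= seg_self[1])
        ]
        donated = [
            r
            for r in by_id[pid].residues
            if r.is_amino_acid and seg_partner and seg_partner[0] <= r.number <= seg_partner[1]
        ]
        core_nums = {(r.number, r.insertion_code) for r in core_res}
        clash = core_nums & {(r.number, r.insertion_code) for r in donated}
        if clash:
            raise ValueError(f"numbering clash between core and donated segment: {sorted(clash)}")
        merged = sorted(core_res + donated, key=lambda r: (r.number, r.insertion_code))
        closed_model = StructureModel(
            models=[[Chain(id=cid, residues=merged)]],
            id=f"{dimer.id}:{cid}:closed",
        )
        out[cid] = (open_model, closed_model)
    return out


def write_label_table(
    swap: SwapAssignment, path: str | Path
) -> None:
    """Per-residue label table as TSV: chain, residue, label, inter, intra."""
    lines = ["chain\tresidue\tlabel\tinter_contacts\tintra_contacts"]
    for (cid, num, icode), label in sorted(swap.labels.items()):
        inter, intra = swap.contact_counts.get((cid, num, icode), (0, 0))
        lines.append(f"{cid}\t{num}{icode}\t{label}\t{inter}\t{intra}")
    Path(path).write_text("\n".join(lines) + "\n")
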