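"""Hierarchical coordinate model for macromolecular structures.

The model mirrors the PDB hierarchy (model / chain / residue / atom) but is
deliberately small: author residue numbering is the *only* numbering exposed,
because the mature-plasma-gelsolin convention (Gly167, Asp187, ...) is how
every downstream metric is specified.  Alternate locations are collapsed to
the highest-occupancy conformer at read time so that all geometric metrics
are deterministic.

File I/O is delegated to :mod:`gemmi` (PDB and mmCIF dialects); sequences go
through Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "Selection",
    "AtomRef",
    "read_structure",
    "write_pdb",
    "read_fasta",
    "select",
    "coords_of",
    "molecular_weight",
    "WATER_NAMES",
]

#: residue names treated as solvent and excluded from interface metrics
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class Atom:
    """A single atom: label, element, position (Å) and crystallographic extras."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue, keyed by author number plus optional insertion code."""

    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.name in _STANDARD_AA


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.id!r}: duplicate residue keys")

    def residue(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (number, insertion_code):
                return r
        return None


@dataclass
class StructureModel:
    """One or more conformers (models) sharing a chain/residue topology.

    ``models[0]`` is the working conformer for single-structure analyses;
    multi-model files (NMR ensembles, trajectory exports) keep every frame.
    """

    models: list[list[Chain]]
    id: str = ""
    source_format: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("StructureModel requires at least one model")

    @property
    def chains(self) -> list[Chain]:
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chain(self, chain_id: str, model: int = 0) -> Chain | None:
        for c in self.models[model]:
            if c.id == chain_id:
                return c
        return None

    def polymer_chains(self, model: int = 0) -> list[Chain]:
        """Chains containing at least one standard amino-acid residue."""
        return [c for c in self.models[model] if any(r.is_amino_acid for r in c.residues)]


@dataclass(frozen=True)
class AtomRef:
    """An atom together with its position in the hierarchy (for contact maps etc.)."""

    chain_id: str
    res_number: int
    insertion_code: str
    res_name: str
    atom: Atom

    @property
    def res_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_number, self.insertion_code)


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection; resolves to a deterministic ordered list.

    ``residue_range`` is inclusive on both ends in author numbering, so
    158–166 selects nine residues.  ``hetero`` of ``None`` keeps everything,
    ``True``/``False`` filter on the HETATM flag.
    """

    chains: tuple[str, ...] | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None
    hetero: bool | None = None
    include_water: bool = True

    def matches(self, ref: AtomRef) -> bool:
        if self.chains is not None and ref.chain_id not in self.chains:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not lo <= ref.res_number <= hi:
                return False
        if self.atom_names is not None and ref.atom.name not in self.atom_names:
            return False
        if self.hetero is not None and ref.atom.is_hetero is not self.hetero:
            return False
        if not self.include_water and ref.res_name in WATER_NAMES:
            return False
        return True


def iter_atoms(model: StructureModel, model_index: int = 0) -> Iterator[AtomRef]:
    """All atoms in deterministic (chain, residue, insertion code, atom) order."""
    for chain in sorted(model.models[model_index], key=lambda c: c.id):
        for res in sorted(chain.residues, key=lambda r: (r.number, r.insertion_code)):
            for atom in res.atoms:
                yield AtomRef(chain.id, res.number, res.insertion_code, res.name, atom)


def select(model: StructureModel, sel: Selection, model_index: int = 0) -> list[AtomRef]:
    """Resolve a :class:`Selection` to an ordered atom list.

    A chain filter that matches nothing yields an empty list with a warning
    rather than an error — masks over partially modeled structures routinely
    reference residues that are absent.
    """
    if sel.chains is not None:
        present = {c.id for c in model.models[model_index]}
        missing = set(sel.chains) - present
        if missing:
            warnings.warn(f"selection references absent chain(s): {sorted(missing)}")
    return [ref for ref in iter_atoms(model, model_index) if sel.matches(ref)]


def coords_of(refs: Sequence[AtomRef]) -> np.ndarray:
    """(n, 3) coordinate array of an atom-ref list."""
    if not refs:
        return np.empty((0, 3))
    return np.array([r.atom.coords for r in refs])


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _dedupe_altlocs(atoms: list[tuple[str, float, Atom]]) -> list[Atom]:
    # keep highest occupancy per atom name; tie -> first encountered
    best: dict[str, tuple[float, int, Atom]] = {}
    for i, (name, occ, atom) in enumerate(atoms):
        if name not in best or occ > best[name][0]:
            best[name] = (occ, i, atom)
    return [a for _, _, a in sorted(best.values(), key=lambda t: t[1])]


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Author residue numbering and heteroatoms (metal ions, citrate, waters)
    are preserved; alternate locations are reduced to the highest-occupancy
    conformer (ties keep the first encountered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in {"mmcif", "cif"}:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown coordinate format: {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown coordinate format" in str(exc):
            raise
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc

    models: list[list[Chain]] = []
    for g_model in st:
        chains: list[Chain] = []
        for g_chain in g_model:
            residues: list[Residue] = []
            for g_res in g_chain:
                raw: list[tuple[str, float, Atom]] = []
                for g_atom in g_res:
                    raw.append(
                        (
                            g_atom.name,
                            g_atom.occ,
                            Atom(
                                name=g_atom.name,
                                element=g_atom.element.name.upper(),
                                coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                                occupancy=min(max(g_atom.occ, 0.0), 1.0),
                                b_factor=g_atom.b_iso,
                                is_hetero=g_res.het_flag == "H",
                            ),
                        )
                    )
                if not raw:
                    continue
                icode = g_res.seqid.icode.strip()
                residues.append(
                    Residue(
                        number=g_res.seqid.num,
                        name=g_res.name,
                        atoms=_dedupe_altlocs(raw),
                        insertion_code=icode,
                    )
                )
            if residues:
                chains.append(Chain(id=g_chain.name, residues=residues))
        if chains:
            models.append(chains)
    if not models:
        raise ValueError(f"{path}: no coordinate records found")
    first_topo = [(c.id, len(c.residues)) for c in models[0]]
    for i, m in enumerate(models[1:], start=2):
        if [(c.id, len(c.residues)) for c in m] != first_topo:
            warnings.warn(f"model {i} topology differs from model 1")
    return StructureModel(models=models, id=st.name or path.stem, source_format=fmt)


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    """Convert to a gemmi Structure (used by the PDB writer)."""
    st = gemmi.Structure()
    st.name = model.id or "MODEL"
    for m_index, chains in enumerate(model.models, start=1):
        g_model = gemmi.Model(m_index)
        for chain in chains:
            g_chain = gemmi.Chain(chain.id)
            for res in chain.residues:
                g_res = gemmi.Residue()
                g_res.name = res.name
                g_res.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
                g_res.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
                for atom in res.atoms:
                    g_atom = gemmi.Atom()
                    g_atom.name = atom.name
                    g_atom.element = gemmi.Element(atom.element.capitalize())
                    g_atom.pos = gemmi.Position(*atom.coords)
                    g_atom.occ = atom.occupancy
                    g_atom.b_iso = atom.b_factor
                    g_res.add_atom(g_atom)
                g_chain.add_residue(g_res)
            g_model.add_chain(g_chain)
        st.add_model(g_model)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (fixture/export writer)."""
    st = to_gemmi(model)
    st.write_pdb(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from a FASTA file as {record id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Sequence mass
# ---------------------------------------------------------------------------

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def molecular_weight(sequence: str) -> float:
    """Average molecular mass of a linear polypeptide, in kDa.

    Sum of average residue masses minus one water per peptide bond; free
    glycine is 0.07507 kDa.  Raises on any letter outside the 20 standard
    one-letter codes, naming the offending position.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for i, letter in enumerate(seq):
        if letter not in _AA_LETTERS:
            raise ValueError(f"unknown amino-acid code {letter!r} at position {i + 1}")
    return _bio_mw(seq, seq_type="protein", monoisotopic=False) / 1000.0
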