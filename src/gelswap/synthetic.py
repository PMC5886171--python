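"""Synthetic inputs with known ground truth for every pipeline stage.

The structural generator builds a minimal contact-topology model of a 3D
domain-swapped dimer from poly-alanine backbones (N, CA, C per residue) on
an idealized β-sheet lattice:

* a *closed monomer* template packs its own N-terminal strand (the future
  swapped segment) into a "slot" beneath a two-strand core;
* the *dimer* places two copies of that fold side by side and exchanges
  the slot strands — each chain's N-terminal segment occupies the partner
  copy's slot, linked to its own core by an elevated hinge bridge kept
  clear of all other atoms.

Strand spacings are chosen so that, at the standard 4.5 Å heavy-atom
contact cutoff, a slot residue touches exactly one partner-core residue
(inter-dominant), a core residue touches three same-chain residues on the
neighbouring strand (intra-dominant), and hinge residues touch nothing
non-local — the clean signature swap detection is built to read.  The toy
is a contact/geometry fixture, not a chemically refined model: bond
lengths along a strand are approximate and side chains are absent.

Curve generators (chromatograms, DLS time courses; melt curves live in
:mod:`gelswap.melt`) are additive-Gaussian-noise models whose analytic
ground truth is recorded alongside every fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import Chromatogram, DlsCalibration, first_order_curve
from .structure import Atom, Chain, Residue, StructureModel

__all__ = [
    "SwapTemplate",
    "GroundTruth",
    "generate_toy_swap",
    "generate_chromatogram",
    "generate_dls_series",
]

_CA_SPACING = 3.5  # along-strand Cα spacing, Å
_SLOT_GAP = 4.45  # slot strand ↔ first core strand separation, Å
_CORE_GAP = 3.6  # core strand ↔ core strand separation, Å
_BRIDGE_Z = 5.0  # hinge bridge elevation, Å
_COPY_GAP = 8.0  # clearance between the two folded copies, Å
_CLASH_LIMIT = 2.0  # heavy-atom clash threshold, Å


@dataclass(frozen=True)
class SwapTemplate:
    """Parameters of the toy swapped assembly.

    ``swap_len`` = 0 produces the negative control: two complete closed
    monomers side by side with no strand exchange.
    """

    swap_len: int = 8
    hinge_len: int = 4
    core_len: int = 17  # residues in the core (two strands + turn)
    seed: int = 0
    jitter_sd: float = 0.0  # optional coordinate jitter, Å

    def __post_init__(self) -> None:
        if self.swap_len < 0 or self.hinge_len < 1 or self.core_len < 5:
            raise ValueError("invalid template: need swap_len ≥ 0, hinge ≥ 1, core ≥ 5")
        if self.swap_len + self.hinge_len + self.core_len < 12:
            raise ValueError("template too small: total length must be ≥ 12 residues")


@dataclass
class GroundTruth:
    """Generator metadata serialized alongside every fixture."""

    swapped_range: tuple[int, int] | None
    hinge_range: tuple[int, int] | None
    n_residues: int
    seed: int
    params: dict = field(default_factory=dict)
    closed_template: StructureModel | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "swapped_range": list(self.swapped_range) if self.swapped_range else None,
                "hinge_range": list(self.hinge_range) if self.hinge_range else None,
                "n_residues": self.n_residues,
                "seed": self.seed,
                "params": self.params,
            },
            indent=2,
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _residue(number: int, ca: np.ndarray, direction: float = 1.0) -> Residue:
    """Poly-ALA residue: N and C flank CA along the strand direction."""
    offset = np.array([1.15 * direction, 0.0, 0.0])
    return Residue(
        number=number,
        name="ALA",
        atoms=[
            Atom(name="N", element="N", coords=ca - offset),
            Atom(name="CA", element="C", coords=ca.copy()),
            Atom(name="C", element="C", coords=ca + offset),
        ],
    )


def _closed_fold_positions(s: int, h: int, core_len: int) -> dict[str, list[np.ndarray]]:
    """Cα positions of the closed fold in its local frame.

    slot: y=0 running +x; core strand1: y=_SLOT_GAP aligned above the slot;
    turn; core strand2: antiparallel at y=_SLOT_GAP+_CORE_GAP; template
    hinge bridges slot end → strand1 start at z=_BRIDGE_Z.
    """
    n1 = s if s > 0 else min(core_len // 2, 6)
    n2 = core_len - 1 - n1
    if n2 < 3:
        raise ValueError("core too small for the requested swap length (need n2 ≥ 3)")
    slot = [np.array([_CA_SPACING * i, 0.0, 0.0]) for i in range(n1)]
    strand1 = [np.array([_CA_SPACING * i, _SLOT_GAP, 0.0]) for i in range(n1)]
    x_top = _CA_SPACING * (n1 - 1)
    turn = [np.array([x_top + 2.8, _SLOT_GAP + _CORE_GAP / 2.0, 0.0])]
    strand2 = [
        np.array([x_top - _CA_SPACING * i, _SLOT_GAP + _CORE_GAP, 0.0]) for i in range(n2)
    ]
    # template hinge: slot end -> strand1 start, elevated
    p0 = np.array([_CA_SPACING * n1, 0.0, _BRIDGE_Z])
    p1 = np.array([-_CA_SPACING, _SLOT_GAP, _BRIDGE_Z])
    hinge = [p0 + (k / (h + 1.0)) * (p1 - p0) for k in range(1, h + 1)]
    return {"slot": slot, "strand1": strand1, "turn": turn, "strand2": strand2, "hinge": hinge}


def _c2(xy_center: tuple[float, float], pos: np.ndarray) -> np.ndarray:
    """180° rotation about the z axis through (cx, cy)."""
    cx, cy = xy_center
    return np.array([2 * cx - pos[0], 2 * cy - pos[1], pos[2]])


def _assemble_chain(
    chain_id: str,
    start_number: int,
    slot_positions: list[np.ndarray],
    hinge_positions: list[np.ndarray],
    core_positions: list[np.ndarray],
    slot_dir: float,
) -> Chain:
    residues = []
    num = start_number
    for pos in slot_positions:
        residues.append(_residue(num, pos, direction=slot_dir))
        num += 1
    for pos in hinge_positions:
        residues.append(_residue(num, pos))
        num += 1
    for pos in core_positions:
        residues.append(_residue(num, pos))
        num += 1
    return Chain(id=chain_id, residues=residues)


def _check_clashes(model: StructureModel, limit: float = _CLASH_LIMIT) -> list[tuple]:
    from .structure import iter_atoms

    refs = list(iter_atoms(model))
    xyz = np.array([r.atom.coords for r in refs])
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    clashes = []
    for i, j in tree.query_pairs(limit):
        a, b = refs[i], refs[j]
        if a.res_key == b.res_key:
            continue
        if a.chain_id == b.chain_id and abs(a.res_number - b.res_number) <= 1:
            continue  # covalently linked neighbours
        clashes.append((a.res_key, b.res_key))
    return clashes


def generate_toy_swap(template: SwapTemplate) -> tuple[StructureModel, GroundTruth]:
    """Two-chain toy assembly with known swapped-segment/hinge ground truth.

    Returns the dimer (chains A and B) and a :class:`GroundTruth` carrying
    the swapped and hinge residue ranges, the closed-monomer template
    coordinates, and the generator parameters.  Deterministic for a fixed
    template (bitwise-identical coordinates).
    """
    s, h, c = template.swap_len, template.hinge_len, template.core_len
    rng = np.random.default_rng(template.seed)

    for attempt in range(5):
        fold = _closed_fold_positions(s, h, c)
        n1 = len(fold["slot"])
        core_pos = fold["strand1"] + fold["turn"] + fold["strand2"]
        x_max = max(p[0] for ps in fold.values() for p in ps) + 1.3
        cx = x_max + _COPY_GAP / 2.0
        cy = (_SLOT_GAP + _CORE_GAP) / 2.0
        center = (cx, cy)

        if s == 0:
            # negative control: two complete closed monomers, no exchange
            length = n1 + h + len(core_pos)
            chain_a = _assemble_chain("A", 1, fold["slot"], fold["hinge"], core_pos, 1.0)
            b_slot = [_c2(center, p) for p in fold["slot"]]
            b_hinge = [_c2(center, p) for p in fold["hinge"]]
            b_core = [_c2(center, p) for p in core_pos]
            chain_b = _assemble_chain("B", 1, b_slot, b_hinge, b_core, -1.0)
            truth_ranges: tuple = (None, None)
        else:
            length = s + h + len(core_pos)
            # chain A: swap strand in copy-2's slot, core in copy 1
            a_slot = [_c2(center, p) for p in fold["slot"]]
            a_p0 = a_slot[-1] + np.array([0.0, 0.0, _BRIDGE_Z])
            a_p1 = np.array([-_CA_SPACING, _SLOT_GAP, _BRIDGE_Z])
            a_hinge = [a_p0 + (k / (h + 1.0)) * (a_p1 - a_p0) for k in range(1, h + 1)]
            chain_a = _assemble_chain("A", 1, a_slot, a_hinge, core_pos, -1.0)
            # chain B: swap strand in copy-1's slot, core in copy 2;
            # its bridge runs below the sheet plane to avoid the A bridge
            b_slot = list(fold["slot"])
            b_p0 = b_slot[-1] + np.array([0.0, 0.0, -_BRIDGE_Z])
            b_p1 = _c2(center, np.array([-_CA_SPACING, _SLOT_GAP, 0.0])) + np.array(
                [0.0, 0.0, -_BRIDGE_Z]
            )
            b_hinge = [b_p0 + (k / (h + 1.0)) * (b_p1 - b_p0) for k in range(1, h + 1)]
            b_core = [_c2(center, p) for p in core_pos]
            chain_b = _assemble_chain("B", 1, b_slot, b_hinge, b_core, 1.0)
            truth_ranges = ((1, s), (s + 1, s + h))

        dimer = StructureModel(models=[[chain_a, chain_b]], id="toy-swap")
        if template.jitter_sd > 0:
            for chain in dimer.chains:
                for res in chain.residues:
                    for atom in res.atoms:
                        atom.coords = atom.coords + rng.normal(
                            0.0, template.jitter_sd, size=3
                        )
        clashes = _check_clashes(dimer)
        if not clashes:
            break
        # jitter and retry; a clash can only arise from user-supplied jitter
        rng = np.random.default_rng(template.seed + attempt + 1)
    else:
        raise RuntimeError(f"could not generate clash-free assembly: clashes at {clashes[:5]}")

    closed = StructureModel(
        models=[[_assemble_chain("A", 1, fold["slot"], fold["hinge"], core_pos, 1.0)]],
        id="toy-closed-monomer",
    )
    truth = GroundTruth(
        swapped_range=truth_ranges[0],
        hinge_range=truth_ranges[1],
        n_residues=length,
        seed=template.seed,
        params={
            "swap_len": s,
            "hinge_len": h,
            "core_len": c,
            "jitter_sd": template.jitter_sd,
        },
        closed_template=closed,
    )
    return dimer, truth


# ---------------------------------------------------------------------------
# Curve generators
# ---------------------------------------------------------------------------

def generate_chromatogram(
    peaks: list[tuple[float, float, float]],
    grid: tuple[float, float] = (8.0, 20.0),
    n_points: int = 600,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Chromatogram, GroundTruth]:
    """Sum-of-Gaussians elution profile.

    ``peaks`` is a list of (elution volume ml, s.d. ml, area); the default
    layout in tests mirrors a gel-filtration run resolving dimer (11.5 ml),
    proteolysis product (12 ml) and monomer (13.5 ml).  Analytic peak areas
    are recorded in the ground truth.
    """
    lo, hi = grid
    if not all(lo < v < hi for v, _w, _a in peaks):
        raise ValueError("all peaks must lie inside the elution grid")
    v = np.linspace(lo, hi, n_points)
    signal = np.full_like(v, baseline)
    for ve, width, area in peaks:
        if width <= 0 or area < 0:
            raise ValueError("peak widths must be positive and areas non-negative")
        signal += area / (width * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((v - ve) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=v.shape)
    chrom = Chromatogram(volume_ml=v, signal=signal, label="synthetic")
    total = sum(a for _v, _w, a in peaks)
    truth = GroundTruth(
        swapped_range=None,
        hinge_range=None,
        n_residues=0,
        seed=seed if seed is not None else -1,
        params={
            "peaks": [list(p) for p in peaks],
            "areas": [a for _v, _w, a in peaks],
            "fractions": [a / total for _v, _w, a in peaks] if total > 0 else [],
            "baseline": baseline,
            "noise_sd": noise_sd,
        },
    )
    return chrom, truth


def generate_dls_series(
    k: float,
    f0: float,
    f_inf: float,
    t_grid: np.ndarray,
    cal: DlsCalibration | None = None,
    noise_sd_nm: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Hydrodynamic-radius time course of a first-order monomer→dimer transition.

    R_H(t) is the inverse calibration of f(t) = f_inf − (f_inf − f0)e^(−kt),
    plus additive Gaussian noise in nm.  Returns (t, R_H, ground truth).
    """
    if k < 0 or not (0 <= f0 <= 1 and 0 <= f_inf <= 1):
        raise ValueError("invalid kinetics parameters")
    cal = cal or DlsCalibration()
    t = np.asarray(t_grid, dtype=float)
    f = first_order_curve(t, k, f0, f_inf)
    r_h = np.asarray(cal.radius(f), dtype=float)
    if noise_sd_nm > 0:
        rng = np.random.default_rng(seed)
        r_h = r_h + rng.normal(0.0, noise_sd_nm, size=t.shape)
    truth = GroundTruth(
        swapped_range=None,
        hinge_range=None,
        n_residues=0,
        seed=seed if seed is not None else -1,
        params={
            "k_per_h": k,
            "f0": f0,
            "f_inf": f_inf,
            "r_h_monomer_nm": cal.r_h_monomer,
            "r_h_dimer_nm": cal.r_h_dimer,
            "noise_sd_nm": noise_sd_nm,
        },
    )
    return t, r_h, truth
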