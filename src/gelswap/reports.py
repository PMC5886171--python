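"""Pipeline stages wired into reproducible report bundles.

``run_swap_report`` produces the table-style characterisation of an
intertwined assembly (swapped/hinge residue counts, interface H-bond and
salt-bridge inventory, buried interaction area, total interaction surface,
masked r.m.s.d. against a closed-monomer reference), plus the per-residue
label table and the contact list.  ``run_biophysics`` wraps the solution
analyses (gel-filtration quantification, DLS kinetics, melt, equilibrium).

Reports are JSON-first; every bundle carries a provenance block (config
hash, package version) and is byte-identical for identical config+inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conformation import pair_ca_by_number, superpose_kabsch
from .interfaces import (
    SasaParams,
    buried_area_open_minus_closed,
    complexation_surface,
    enumerate_hbonds,
)
from .kinetics import (
    Chromatogram,
    DlsCalibration,
    calibrate_dls,
    fit_first_order,
    fit_kd,
    integrate_peaks,
)
from .melt import MeltCurve, find_tm
from .structure import Selection, StructureModel, read_structure, select
from .swap import classify_interfaces, detect_swap, reconstruct_monomers, write_label_table

logger = logging.getLogger("gelswap")

__all__ = ["RunConfig", "run_swap_report", "run_biophysics", "load_xy_table"]


@dataclass
class RunConfig:
    """Serializable knobs for a pipeline run; archived with every bundle."""

    contact_cutoff: float = 4.5
    min_segment: int = 4
    sasa_probe: float = 1.4
    sasa_n_points: int = 960
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 90.0
    salt_bridge_cutoff: float = 4.0
    superpose_exclude: list[tuple[int, int]] = field(default_factory=list)
    dls_r_h_monomer: float = 2.0
    dls_r_h_dimer: float = 3.0
    melt_transitions: int = 1
    melt_smoothing_window: int = 9
    seed: int = 0

    def sasa_params(self) -> SasaParams:
        return SasaParams(probe=self.sasa_probe, n_points=self.sasa_n_points)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"package": "gelswap", "version": __version__, "config_sha256": self.digest()}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.superpose_exclude = [tuple(r) for r in cfg.superpose_exclude]
        return cfg


def run_swap_report(
    dimer_path: str | Path,
    reference_path: str | Path | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full structural characterisation of a two-chain swapped assembly.

    Raises ``ValueError`` ("no reciprocal swap detected") for non-swapped
    input.  When ``out_dir`` is given, writes report.json, labels.tsv and
    contacts.tsv there.
    """
    config = config or RunConfig()
    dimer = read_structure(dimer_path)
    swap = detect_swap(dimer, min_segment=config.min_segment, cutoff=config.contact_cutoff)
    if not swap.is_swapped:
        raise ValueError("no reciprocal swap detected in the input assembly")
    interfaces = classify_interfaces(dimer, swap, cutoff=config.contact_cutoff)
    monomers = reconstruct_monomers(dimer, swap)
    params = config.sasa_params()

    chain_ids = sorted(monomers)
    per_subunit: dict[str, dict] = {}
    for cid in chain_ids:
        open_m, closed_m = monomers[cid]
        open_atoms = [
            r for r in select(open_m, Selection(include_water=False)) if not r.atom.is_hetero
        ]
        closed_atoms = [
            r for r in select(closed_m, Selection(include_water=False)) if not r.atom.is_hetero
        ]
        buried = buried_area_open_minus_closed(open_atoms, closed_atoms, params)
        total_surface = complexation_surface(dimer, cid, params)
        per_subunit[cid] = {
            "buried_interaction_area_A2": round(buried, 1),
            "total_interaction_surface_A2": round(total_surface, 1),
        }

    hbonds = enumerate_hbonds(
        dimer,
        inter_chain_only=True,
        d_max=config.hbond_d_max,
        angle_min=config.hbond_angle_min,
        salt_bridge_cutoff=config.salt_bridge_cutoff,
    )

    report: dict = {
        "provenance": config.provenance(),
        "assembly": str(Path(dimer_path).name),
        "is_swapped": True,
        "per_chain": {
            cid: {
                "swapped_segment": list(swap.swapped_segment[cid]),
                "n_swapped": swap.n_swapped(cid),
                "hinge": list(swap.hinge[cid]) if swap.hinge[cid] else None,
                "n_hinge": swap.n_hinge(cid),
                **per_subunit[cid],
            }
            for cid in chain_ids
        },
        "interface": {
            "n_o_interface_contacts": interfaces.n_o,
            "n_c_interface_contacts": interfaces.n_c,
            "n_intermolecular_hbonds": len(hbonds),
            "n_salt_bridges": sum(1 for h in hbonds if h.is_salt_bridge),
        },
    }

    if reference_path is not None:
        reference = read_structure(reference_path)
        ref_chain = reference.polymer_chains()[0].id
        mob, tgt, kept = pair_ca_by_number(
            dimer, chain_ids[0], reference, ref_chain, exclude_ranges=config.superpose_exclude
        )
        sup = superpose_kabsch(mob, tgt, selection=f"CA x{len(kept)} masked")
        report["superposition_vs_reference"] = {
            "rmsd_A": round(sup.rmsd, 2),
            "n_ca_atoms": sup.n_atoms,
            "excluded_ranges": [list(r) for r in config.superpose_exclude],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        write_label_table(swap, out / "labels.tsv")
        from .interfaces import InterfaceReport

        InterfaceReport(hbonds=hbonds).write_contacts_tsv(out / "contacts.tsv")
        logger.info("swap report written to %s", out)
    return report


def load_xy_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV/TSV (header required) → (x, y) arrays."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pandas raises several flavours on malformed input
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: expected a two-column table with a header row")
    bad = df.iloc[:, :2].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed row {int(bad.idxmax()) + 2}")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def run_biophysics(
    input_path: str | Path,
    mode: str,
    config: RunConfig | None = None,
    windows: dict[str, tuple[float, float]] | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Fit report for a solution-state curve file.

    Modes: ``gf`` (chromatogram peak fractions over elution-volume windows),
    ``dls`` (R_H time course → calibration → first-order fit), ``melt``
    (derivative-maximum T_m), ``equilibrium`` (concentration vs dimer
    fraction → Kd).
    """
    config = config or RunConfig()
    x, y = load_xy_table(input_path)
    result: dict
    if mode == "gf":
        if not windows:
            raise ValueError("gf mode needs labeled elution-volume windows")
        chrom = Chromatogram(volume_ml=x, signal=y, label=str(input_path))
        fractions = integrate_peaks(chrom, windows)
        result = {"mode": "gf", "fractions": fractions.fractions, "areas": fractions.areas}
    elif mode == "dls":
        cal = DlsCalibration(config.dls_r_h_monomer, config.dls_r_h_dimer)
        f = calibrate_dls(y, cal)
        fit = fit_first_order(x, f)
        result = {"mode": "dls", "fit": fit.to_dict()}
    elif mode == "melt":
        curve = MeltCurve(temperature_c=x, signal=y, label=str(input_path))
        melt = find_tm(
            curve,
            n_transitions=config.melt_transitions,
            smoothing_window=config.melt_smoothing_window,
        )
        result = {"mode": "melt", **melt.to_dict()}
    elif mode == "equilibrium":
        model = fit_kd(list(zip(x, y)))
        result = {"mode": "equilibrium", **model.to_dict()}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result["provenance"] = config.provenance()
    result["input"] = str(Path(input_path).name)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
        logger.info("%s report written to %s", mode, out_path)
    return result
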