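"""Shared fixtures: toy structures and fetch support for network-tier tests."""

from __future__ import annotations

import urllib.request
from pathlib import Path

import numpy as np
import pytest

from gelswap.synthetic import SwapTemplate, generate_toy_swap

DATA_DIR = Path(__file__).parent / "data"
STRUCTURE_CACHE = DATA_DIR / "structures"


@pytest.fixture(scope="session")
def toy_swap():
    """Default toy swapped dimer (8-residue exchange, 4-residue hinge) + truth."""
    return generate_toy_swap(SwapTemplate(swap_len=8, hinge_len=4, core_len=17, seed=0))


@pytest.fixture(scope="session")
def toy_nonswap():
    """Side-by-side pair of closed monomers (negative control)."""
    return generate_toy_swap(SwapTemplate(swap_len=0, hinge_len=4, core_len=17, seed=0))


def fetch_structure(pdb_id: str) -> Path:
    """Return a local PDB file, downloading from RCSB if needed.

    Pre-downloaded files in tests/data/structures/ are used as-is, so the
    network tier can run offline once the structures have been fetched.
    """
    STRUCTURE_CACHE.mkdir(parents=True, exist_ok=True)
    path = STRUCTURE_CACHE / f"{pdb_id.lower()}.pdb"
    if path.exists():
        return path
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=10) as resp:
            path.write_bytes(resp.read())
    except Exception as exc:
        raise RuntimeError(
            f"structure {pdb_id} unavailable: no copy in {STRUCTURE_CACHE} and download "
            f"failed ({exc}); this check needs network access or a pre-downloaded file"
        ) from exc
    return path


def fetch_uniprot(accession: str) -> str:
    """Return the full-length UniProt sequence, from cache or the REST API."""
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    path = DATA_DIR / f"{accession.lower()}.fasta"
    if not path.exists():
        url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
        try:
            with urllib.request.urlopen(url, timeout=10) as resp:
                path.write_bytes(resp.read())
        except Exception as exc:
            raise RuntimeError(
                f"sequence {accession} unavailable: no copy in {DATA_DIR} and download "
                f"failed ({exc}); this check needs network access or a pre-downloaded file"
            ) from exc
    lines = path.read_text().splitlines()
    return "".join(l.strip() for l in lines if not l.startswith(">"))
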