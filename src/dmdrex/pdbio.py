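"""PDB import/export for the Cα-bead model (via biotite).

Beads are written as CA atom records, one residue per bead with 1-based
numbering; each topology segment gets its own chain identifier so the
segment layout survives the round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .topology import ChainTopology

__all__ = ["write_beads_pdb", "read_beads_pdb"]

_CHAIN_IDS = "ABCDEFGHIJ"


def _segment_chain_map(topology: ChainTopology) -> dict[str, str]:
    return {
        label: _CHAIN_IDS[k % len(_CHAIN_IDS)]
        for k, (label, _, _) in enumerate(topology.segments)
    }


def write_beads_pdb(
    path: str | Path, coords: np.ndarray, topology: ChainTopology
) -> None:
    """Write one bead conformation as a CA-only PDB file."""
    x = np.asarray(coords, dtype=float)
    n = topology.n_beads
    if x.shape != (n, 3):
        raise ValueError(f"expected ({n}, 3) coordinates, got {x.shape}")
    chain_of = _segment_chain_map(topology)
    atoms = struc.AtomArray(n)
    atoms.coord = x
    atoms.atom_name = np.full(n, "CA")
    atoms.res_name = np.full(n, "ALA")
    atoms.element = np.full(n, "C")
    atoms.res_id = np.arange(1, n + 1)
    atoms.chain_id = np.array([chain_of[topology.segment_of(i)] for i in range(n)])
    atoms.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_beads_pdb(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read CA coordinates (and chain ids) back from a PDB file."""
    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    return np.asarray(ca.coord, dtype=float), np.asarray(ca.chain_id)
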