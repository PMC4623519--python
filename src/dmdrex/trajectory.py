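"""Trajectory container with an HDF5 store and a plain-text XYZ exporter.

Per frame: time (float64, t.u.), n×3 positions (float32 on disk, Å),
potential and kinetic energy (float64, kcal/mol).  The file header records
the temperature, seed and a topology hash so a store can be matched back to
the run that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_beads, 3)
    potential_energy: np.ndarray
    kinetic_energy: np.ndarray
    temperature: float
    seed: int
    n_events: int = 0
    events: list = field(default_factory=list)
    topology_hash: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential_energy + self.kinetic_energy

    def slice(self, start: int, stop: int | None = None) -> "Trajectory":
        sl = slice(start, stop)
        return Trajectory(
            self.times[sl],
            self.positions[sl],
            self.potential_energy[sl],
            self.kinetic_energy[sl],
            self.temperature,
            self.seed,
            self.n_events,
            [],
            self.topology_hash,
        )

    @staticmethod
    def concatenate(parts: list["Trajectory"]) -> "Trajectory":
        first = parts[0]
        return Trajectory(
            np.concatenate([p.times for p in parts]),
            np.concatenate([p.positions for p in parts]),
            np.concatenate([p.potential_energy for p in parts]),
            np.concatenate([p.kinetic_energy for p in parts]),
            first.temperature,
            first.seed,
            sum(p.n_events for p in parts),
            [],
            first.topology_hash,
        )

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["temperature"] = self.temperature
            h5.attrs["seed"] = self.seed
            h5.attrs["n_events"] = self.n_events
            h5.attrs["topology_hash"] = self.topology_hash
            h5.create_dataset("times", data=self.times)
            h5.create_dataset(
                "positions", data=self.positions.astype(np.float32)
            )
            h5.create_dataset("potential_energy", data=self.potential_energy)
            h5.create_dataset("kinetic_energy", data=self.kinetic_energy)

    @staticmethod
    def load(path: str | Path) -> "Trajectory":
        with h5py.File(path, "r") as h5:
            return Trajectory(
                times=h5["times"][:],
                positions=h5["positions"][:].astype(np.float64),
                potential_energy=h5["potential_energy"][:],
                kinetic_energy=h5["kinetic_energy"][:],
                temperature=float(h5.attrs["temperature"]),
                seed=int(h5.attrs["seed"]),
                n_events=int(h5.attrs["n_events"]),
                topology_hash=str(h5.attrs["topology_hash"]),
            )

    def to_xyz(self, path: str | Path, element: str = "C") -> None:
        """Plain-text XYZ export for interoperability with viewers."""
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"{self.n_beads}\n")
                fh.write(f"t={self.times[f]:.3f} pe={self.potential_energy[f]:.6f}\n")
                for x, y, z in self.positions[f]:
                    fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")


def topology_hash(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]
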