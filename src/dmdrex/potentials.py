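"""Piecewise-constant pair potentials and the per-pair interaction table.

The engine's entire force-field abstraction is the multistep square-well
potential: a sorted list of distance thresholds with a constant energy level
between consecutive thresholds.  Particles move ballistically inside a shell
and exchange energy instantaneously when they cross a threshold.

Three pair classes cover the coarse-grained model:

* hard core only — a single infinite inner level,
* native-contact well — hard core plus one attractive level,
* covalent bond — a narrow confining well (infinite on *both* sides), the
  standard square-well realization of a fixed-length bond.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepPotential", "InteractionModel", "pair_index"]

INF = math.inf


@dataclass(frozen=True)
class StepPotential:
    """A multistep square-well pair potential.

    Parameters
    ----------
    thresholds
        Strictly increasing positive distances d_1 < ... < d_K (Å).
    energies
        K+1 energy levels (kcal/mol); ``energies[k]`` applies between
        d_k and d_{k+1}.  The innermost level may be ``+inf`` (hard core).
        The outermost level must be 0, or ``+inf`` for a confining well
        (covalent bond).
    """

    thresholds: tuple[float, ...]
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        en = tuple(float(e) for e in self.energies)
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "energies", en)
        if len(en) != len(thr) + 1:
            raise ValueError("need exactly len(thresholds)+1 energy levels")
        if not thr:
            raise ValueError("at least one threshold required")
        if any(t <= 0 for t in thr):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        inner = en[:-1]
        if any(math.isinf(e) for e in inner[1:]):
            raise ValueError("only the innermost level may be infinite")
        if not (en[-1] == 0.0 or math.isinf(en[-1])):
            raise ValueError("outermost level must be 0 (or +inf for a bond)")

    @property
    def n_shells(self) -> int:
        return len(self.energies)

    @property
    def confining(self) -> bool:
        """True when the outermost wall reflects (covalent-bond well)."""
        return math.isinf(self.energies[-1])

    def shell_of(self, distance: float) -> int:
        """Index of the shell containing ``distance`` (0 = innermost)."""
        return int(np.searchsorted(self.thresholds, distance, side="right"))

    def energy_at(self, distance: float) -> float:
        return self.energies[self.shell_of(distance)]

    # -- constructors -------------------------------------------------

    @staticmethod
    def hard_core(diameter: float) -> "StepPotential":
        return StepPotential((diameter,), (INF, 0.0))

    @staticmethod
    def bond(length: float, tolerance: float) -> "StepPotential":
        """Confining square well at length·(1±tolerance)."""
        if not (0 < tolerance < 1):
            raise ValueError("bond tolerance must lie in (0, 1)")
        return StepPotential(
            (length * (1 - tolerance), length * (1 + tolerance)),
            (INF, 0.0, INF),
        )

    @staticmethod
    def native_well(core: float, outer: float, depth: float) -> "StepPotential":
        """Hard core plus a single attractive well reaching ``outer``."""
        if depth < 0:
            raise ValueError("well depth must be non-negative")
        return StepPotential((core, outer), (INF, -depth, 0.0))


def pair_index(i: int, j: int, n: int) -> int:
    """Flat index of the unordered pair (i<j) in the packed upper triangle."""
    if i > j:
        i, j = j, i
    return i * n - i * (i + 1) // 2 + (j - i - 1)


# sentinel energy used for +inf in the packed float arrays handed to numba
_BIG = 1e30


@dataclass
class InteractionModel:
    """Assignment of a :class:`StepPotential` to every bead pair.

    Pairs not explicitly assigned interact through the default hard-core
    potential.  The packed array form consumed by the event loop is built
    lazily and cached.
    """

    n_beads: int
    default: StepPotential
    pair_potentials: dict[tuple[int, int], StepPotential] = field(default_factory=dict)
    pair_class: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("need at least two beads")
        self._packed: tuple[np.ndarray, ...] | None = None

    def set_pair(self, i: int, j: int, pot: StepPotential, kind: str = "custom") -> None:
        if i == j or not (0 <= i < self.n_beads and 0 <= j < self.n_beads):
            raise ValueError(f"invalid pair ({i}, {j})")
        key = (min(i, j), max(i, j))
        self.pair_potentials[key] = pot
        self.pair_class[key] = kind
        self._packed = None

    def potential(self, i: int, j: int) -> StepPotential:
        key = (min(i, j), max(i, j))
        return self.pair_potentials.get(key, self.default)

    def pairs_of_class(self, kind: str) -> list[tuple[int, int]]:
        return sorted(k for k, v in self.pair_class.items() if v == kind)

    @property
    def n_pairs(self) -> int:
        return self.n_beads * (self.n_beads - 1) // 2

    # -- energies ------------------------------------------------------

    def potential_energy(self, positions: np.ndarray) -> float:
        """Total pair energy of a configuration (O(n²) direct sum)."""
        pos = np.asarray(positions, dtype=float)
        total = 0.0
        for i in range(self.n_beads):
            d = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
            for off, dist in enumerate(d):
                total += self.potential(i, i + 1 + off).energy_at(float(dist))
        return total

    def initial_shells(self, positions: np.ndarray) -> np.ndarray:
        """Shell index of every pair for a configuration (consistency seed)."""
        pos = np.asarray(positions, dtype=float)
        shells = np.zeros(self.n_pairs, dtype=np.int64)
        for i in range(self.n_beads):
            for j in range(i + 1, self.n_beads):
                d = float(np.linalg.norm(pos[j] - pos[i]))
                shells[pair_index(i, j, self.n_beads)] = self.potential(i, j).shell_of(d)
        return shells

    # -- packed form for the event loop --------------------------------

    def packed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flat arrays (offsets, n_thresholds, confining, thresholds, energies).

        ``offsets[p]`` indexes the first threshold of pair p in the flat
        threshold array; energies for pair p occupy
        ``energies[offsets[p]+p : offsets[p]+p+n_thr+1]`` (one extra level
        per pair).  ``+inf`` is encoded as 1e30 so the arrays stay float64.
        """
        if self._packed is not None:
            return self._packed
        n = self.n_beads
        offsets = np.zeros(self.n_pairs, dtype=np.int64)
        nthr = np.zeros(self.n_pairs, dtype=np.int64)
        confin = np.zeros(self.n_pairs, dtype=np.bool_)
        thr_list: list[float] = []
        en_list: list[float] = []
        p = 0
        for i in range(n):
            for j in range(i + 1, n):
                pot = self.potential(i, j)
                offsets[p] = len(thr_list)
                nthr[p] = len(pot.thresholds)
                confin[p] = pot.confining
                thr_list.extend(pot.thresholds)
                en_list.extend(min(e, _BIG) for e in pot.energies)
                p += 1
        self._packed = (
            offsets,
            nthr,
            confin,
            np.asarray(thr_list, dtype=np.float64),
            np.asarray(en_list, dtype=np.float64),
        )
        return self._packed

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        """Documented plain-text table of the pair potentials."""

        def enc(e: float) -> float | str:
            return "inf" if math.isinf(e) else e

        records = []
        for (i, j), pot in sorted(self.pair_potentials.items()):
            records.append(
                {
                    "i": i + 1,
                    "j": j + 1,
                    "class": self.pair_class[(i, j)],
                    "thresholds_A": list(pot.thresholds),
                    "energies_kcal_mol": [enc(e) for e in pot.energies],
                }
            )
        doc = {
            "format": "dmdrex step-potential table v1 (1-based bead ids)",
            "n_beads": self.n_beads,
            "default": {
                "thresholds_A": list(self.default.thresholds),
                "energies_kcal_mol": [enc(e) for e in self.default.energies],
            },
            "pairs": records,
        }
        return json.dumps(doc, indent=1)

    @staticmethod
    def from_json(text: str) -> "InteractionModel":
        doc = json.loads(text)

        def dec(vals: list) -> tuple[float, ...]:
            return tuple(INF if v == "inf" else float(v) for v in vals)

        model = InteractionModel(
            n_beads=int(doc["n_beads"]),
            default=StepPotential(
                tuple(doc["default"]["thresholds_A"]),
                dec(doc["default"]["energies_kcal_mol"]),
            ),
        )
        for rec in doc["pairs"]:
            model.set_pair(
                rec["i"] - 1,
                rec["j"] - 1,
                StepPotential(tuple(rec["thresholds_A"]), dec(rec["energies_kcal_mol"])),
                kind=rec["class"],
            )
        return model
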