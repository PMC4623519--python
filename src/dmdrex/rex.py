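"""Replica exchange over a temperature ladder.

Parallel single-temperature runs are periodically coupled by Metropolis
swaps of *temperatures* between adjacent replicas (velocities rescaled by
√(T_new/T_old)), which is statistically equivalent to swapping
configurations and cheaper.  Sweeps alternate between even and odd
adjacent pairs.  The full swap and temperature-assignment history is kept
so replica mobility through temperature space can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .engine import SystemState
from .potentials import InteractionModel
from .trajectory import Trajectory
from .units import KB

__all__ = [
    "TemperatureLadder",
    "SwapRecord",
    "ReplicaEnsemble",
    "build_ladder",
    "attempt_swap",
    "run_rex",
    "replica_mobility",
    "run_rex_two_level",
]


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing reduced temperatures, kcal/(mol·kB)."""

    temperatures: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.temperatures)
        object.__setattr__(self, "temperatures", t)
        if not t:
            raise ValueError("ladder must not be empty")
        if any(x <= 0 for x in t):
            raise ValueError("temperatures must be positive")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)

    def __getitem__(self, k: int) -> float:
        return self.temperatures[k]

    @property
    def kelvin(self) -> tuple[float, ...]:
        return tuple(t / KB for t in self.temperatures)


def build_ladder(t_min: float, t_max: float, increment: float) -> TemperatureLadder:
    """Inclusive arithmetic temperature grid.

    Rejects spans that are not an integer number of increments (to 1e-9).
    """
    if t_min >= t_max:
        raise ValueError("t_min must be below t_max")
    if increment <= 0:
        raise ValueError("increment must be positive")
    span = (t_max - t_min) / increment
    n_steps = round(span)
    if abs(span - n_steps) > 1e-9 * max(1.0, span):
        raise ValueError(
            f"span {t_max - t_min} is not an integer multiple of {increment}"
        )
    temps = tuple(t_min + k * increment for k in range(n_steps + 1))
    return TemperatureLadder(temps)


def attempt_swap(
    beta_i: float, beta_j: float, e_i: float, e_j: float, rng: np.random.Generator
) -> bool:
    """Metropolis acceptance for exchanging two replicas' temperatures.

    Accepts with probability min(1, exp[(β_i − β_j)(E_i − E_j)]).
    """
    if beta_i <= 0 or beta_j <= 0:
        raise ValueError("inverse temperatures must be positive")
    exponent = (beta_i - beta_j) * (e_i - e_j)
    if exponent >= 0:
        return True
    return rng.random() < math.exp(exponent)


@dataclass(frozen=True)
class SwapRecord:
    time: float
    replica_i: int  # replica currently at ladder slot k
    replica_j: int  # replica currently at ladder slot k+1
    slot: int  # lower ladder slot of the attempted pair
    e_i: float
    e_j: float
    accepted: bool


@dataclass
class ReplicaEnsemble:
    """Results of a replica-exchange run.

    ``trajectories[r]`` is replica r's concatenated trajectory;
    ``slot_history[s, r]`` is the ladder slot replica r occupied during
    sweep s; ``energy_series[k]`` collects potential-energy samples taken
    while *any* replica held ladder temperature k (one value per frame).
    """

    ladder: TemperatureLadder
    trajectories: list[Trajectory]
    slot_history: np.ndarray  # (n_sweeps, n_replicas) int
    swap_records: list[SwapRecord]
    energy_series: list[np.ndarray]
    energy_times: list[np.ndarray]
    seed: int = 0
    swap_interval: float = np.nan

    @property
    def n_replicas(self) -> int:
        return len(self.ladder)

    def frames_at_slot(self, slot: int) -> tuple[np.ndarray, np.ndarray]:
        """All frames sampled while any replica held ladder slot ``slot``.

        Returns (times, positions) pooled over replicas, time-ordered.
        A frame at time t belongs to the sweep that ended at or after t.
        """
        n_sweeps = self.slot_history.shape[0]
        times_parts, pos_parts = [], []
        for r in range(self.n_replicas):
            traj = self.trajectories[r]
            t = traj.times
            sweep = np.clip(
                np.ceil(t / self.swap_interval - 1e-12).astype(int) - 1, 0, n_sweeps - 1
            )
            keep = self.slot_history[sweep, r] == slot
            times_parts.append(t[keep])
            pos_parts.append(traj.positions[keep])
        times = np.concatenate(times_parts)
        pos = np.concatenate(pos_parts)
        order = np.argsort(times, kind="stable")
        return times[order], pos[order]

    def swap_acceptance_rate(self) -> float:
        if not self.swap_records:
            return math.nan
        return float(np.mean([r.accepted for r in self.swap_records]))

    def swap_history_tsv(self) -> str:
        lines = ["time\tslot\treplica_i\treplica_j\tE_i\tE_j\taccepted"]
        for r in self.swap_records:
            lines.append(
                f"{r.time:.6g}\t{r.slot}\t{r.replica_i}\t{r.replica_j}\t"
                f"{r.e_i:.10g}\t{r.e_j:.10g}\t{int(r.accepted)}"
            )
        return "\n".join(lines) + "\n"


def run_rex(
    model: InteractionModel,
    initial_state: SystemState,
    ladder: TemperatureLadder,
    n_timesteps: float,
    swap_interval: float = 1000.0,
    thermostat_rate: float = 0.1,
    frame_interval: float = 50.0,
    seed: int = 0,
    window: float = 2.0,
) -> ReplicaEnsemble:
    """Replica-exchange DMD: one replica per ladder temperature.

    Every replica starts from a copy of ``initial_state`` with
    Maxwell–Boltzmann velocities at its own temperature.  Replicas advance
    independently between swap barriers; at each barrier adjacent pairs
    (even sweeps: slots (0,1),(2,3)…; odd sweeps: (1,2),(3,4)…) attempt a
    Metropolis temperature exchange.  Replicas run sequentially, so results
    are reproducible bit-for-bit for a given seed.
    """
    if n_timesteps <= 0:
        raise ValueError("n_timesteps must be positive")
    if swap_interval <= 0:
        raise ValueError("swap_interval must be positive")
    n_rep = len(ladder)
    n_sweeps = int(round(n_timesteps / swap_interval))
    if n_sweeps < 1 or abs(n_sweeps * swap_interval - n_timesteps) > 1e-9 * n_timesteps:
        raise ValueError("n_timesteps must be a positive multiple of swap_interval")

    rng = np.random.default_rng(seed)
    # replica r currently holds ladder slot slot_of[r]
    slot_of = np.arange(n_rep)
    rep_at = np.arange(n_rep)  # inverse map: replica sitting at slot k

    states: list[SystemState] = []
    for r in range(n_rep):
        st = initial_state.copy()
        if st.shells is None:
            st.bind_model(model)
        st.thermalize(ladder[slot_of[r]], rng)
        states.append(st)

    parts: list[list[Trajectory]] = [[] for _ in range(n_rep)]
    slot_history = np.empty((n_sweeps, n_rep), dtype=np.int64)
    swap_records: list[SwapRecord] = []
    e_series: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    e_times: list[list[np.ndarray]] = [[] for _ in range(n_rep)]

    for sweep in range(n_sweeps):
        slot_history[sweep] = slot_of
        for r in range(n_rep):
            temp = ladder[slot_of[r]]
            seg_seed = int(rng.integers(2**31))
            traj = engine.run(
                states[r],
                model,
                temperature=temp,
                n_timesteps=swap_interval,
                thermostat_rate=thermostat_rate,
                frame_interval=frame_interval,
                seed=seg_seed,
                window=window,
            )
            # drop each segment's t0 frame (duplicates the previous end)
            keep = traj if sweep == 0 else traj.slice(1)
            parts[r].append(keep)
            e_series[slot_of[r]].append(keep.potential_energy)
            e_times[slot_of[r]].append(keep.times)

        # swap barrier
        t_now = (sweep + 1) * swap_interval
        first = 0 if sweep % 2 == 0 else 1
        for k in range(first, n_rep - 1, 2):
            ri, rj = rep_at[k], rep_at[k + 1]
            e_i = states[ri].potential_energy
            e_j = states[rj].potential_energy
            beta_i = 1.0 / ladder[k]
            beta_j = 1.0 / ladder[k + 1]
            ok = attempt_swap(beta_i, beta_j, e_i, e_j, rng)
            swap_records.append(
                SwapRecord(t_now, int(ri), int(rj), k, e_i, e_j, ok)
            )
            if ok:
                # exchange temperatures; rescale velocities
                states[ri].velocities *= math.sqrt(ladder[k + 1] / ladder[k])
                states[rj].velocities *= math.sqrt(ladder[k] / ladder[k + 1])
                slot_of[ri], slot_of[rj] = k + 1, k
                rep_at[k], rep_at[k + 1] = rj, ri

    trajectories = [Trajectory.concatenate(parts[r]) for r in range(n_rep)]
    return ReplicaEnsemble(
        ladder=ladder,
        trajectories=trajectories,
        slot_history=slot_history,
        swap_records=swap_records,
        energy_series=[np.concatenate(s) for s in e_series],
        energy_times=[np.concatenate(s) for s in e_times],
        seed=seed,
        swap_interval=float(swap_interval),
    )


def replica_mobility(ensemble: ReplicaEnsemble) -> tuple[np.ndarray, float, float]:
    """Distinct ladder temperatures visited per replica (count, mean, sd)."""
    hist = ensemble.slot_history
    counts = np.array(
        [len(np.unique(hist[:, r])) for r in range(hist.shape[1])], dtype=float
    )
    return counts, float(counts.mean()), float(counts.std())


# ---------------------------------------------------------------------------
# direct-sampling REX on a two-level system (detailed-balance harness)
# ---------------------------------------------------------------------------


def run_rex_two_level(
    energies,
    degeneracies,
    ladder: TemperatureLadder,
    n_sweeps: int,
    seed: int = 0,
    return_acceptance: bool = False,
):
    """Replica exchange where each replica is an exact Gibbs sampler of a
    two-level system.

    Between swap attempts every replica redraws its state from the
    Boltzmann law at its current temperature; swaps then follow the same
    Metropolis rule as the DMD ensemble.  Returns per-temperature sampled
    energy series — useful to verify that exchange does not perturb the
    equilibrium marginals.
    """
    from .models import two_level_stats

    rng = np.random.default_rng(seed)
    n_rep = len(ladder)
    slot_of = np.arange(n_rep)
    rep_at = np.arange(n_rep)
    e = np.zeros(n_rep)  # current energy per replica
    out: list[list[float]] = [[] for _ in range(n_rep)]
    attempts = 0
    accepts = 0
    for sweep in range(n_sweeps):
        for r in range(n_rep):
            t = ladder[slot_of[r]]
            p1, _, _ = two_level_stats(energies, degeneracies, t)
            e[r] = energies[1] if rng.random() < p1 else energies[0]
            out[slot_of[r]].append(e[r])
        first = 0 if sweep % 2 == 0 else 1
        for k in range(first, n_rep - 1, 2):
            ri, rj = rep_at[k], rep_at[k + 1]
            attempts += 1
            if attempt_swap(1.0 / ladder[k], 1.0 / ladder[k + 1], e[ri], e[rj], rng):
                accepts += 1
                slot_of[ri], slot_of[rj] = k + 1, k
                rep_at[k], rep_at[k + 1] = rj, ri
    series = {ladder[k]: np.asarray(out[k]) for k in range(n_rep)}
    if return_acceptance:
        return series, accepts / max(attempts, 1)
    return series
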