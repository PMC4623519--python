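"""Event-driven discrete molecular dynamics over square-well potentials.

Between events every bead moves ballistically; at an event the radial
component of the relative velocity of one pair changes instantaneously so
that energy, linear momentum and angular momentum are conserved (the
tangential component is untouched).  Temperature is imposed by an Andersen
thermostat: Poisson-scheduled full velocity redraws of single beads.

The hot loop lives in :mod:`dmdrex._kernels`; this module provides the
object-level API and the per-operation functions used directly in tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .potentials import InteractionModel, StepPotential, pair_index
from .trajectory import Trajectory

__all__ = [
    "SystemState",
    "Event",
    "predict_pair_event",
    "resolve_collision",
    "andersen_kick",
    "run",
]

EVENT_KINDS = {
    _kernels.K_CROSS_OUT: "shell_crossing",
    _kernels.K_CROSS_IN: "shell_crossing",
    _kernels.K_REFLECT_OUT: "bond_wall",
    _kernels.K_REFLECT_IN: "core_bounce",
    _kernels.K_KICK: "thermostat",
}


@dataclass
class SystemState:
    """Bead positions/velocities plus event bookkeeping for one replica."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    time: float = 0.0
    shells: np.ndarray | None = None
    potential_energy: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must share a shape")
        if self.positions.shape[0] != self.masses.shape[0]:
            raise ValueError("one mass per bead required")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))

    @property
    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            self.time,
            None if self.shells is None else self.shells.copy(),
            self.potential_energy,
        )

    def bind_model(self, model: InteractionModel) -> None:
        """Recompute shell indices and potential energy from positions."""
        self.shells = model.initial_shells(self.positions)
        self.potential_energy = model.potential_energy(self.positions)

    def thermalize(self, temperature: float, rng: np.random.Generator) -> None:
        """Draw Maxwell–Boltzmann velocities at a reduced temperature."""
        sig = np.sqrt(temperature / self.masses)
        self.velocities = rng.normal(size=self.positions.shape) * sig[:, None]


@dataclass(frozen=True)
class Event:
    """A scheduled or processed discontinuity."""

    time: float
    kind: str  # core_bounce | shell_crossing | bond_wall | thermostat | end
    i: int
    j: int = -1
    direction: int = 0  # +1 outward, -1 inward (pair events)


def _pair_geometry(state: SystemState, pair: tuple[int, int]):
    i, j = pair
    r = state.positions[i] - state.positions[j]
    v = state.velocities[i] - state.velocities[j]
    return r, v


def predict_pair_event(
    state: SystemState, pair: tuple[int, int], potential: StepPotential
) -> Event | None:
    """Earliest future boundary crossing of one pair, or None.

    Solves |r + v t|² = d² for the boundaries adjacent to the pair's
    current shell and returns the earliest positive root.
    """
    i, j = pair
    r, v = _pair_geometry(state, pair)
    dist = float(np.linalg.norm(r))
    s = potential.shell_of(dist)
    on_boundary = any(abs(dist - t) < 1e-9 for t in potential.thresholds)
    if state.shells is not None:
        recorded = int(state.shells[pair_index(i, j, state.n_beads)])
        if recorded != s:
            if on_boundary:
                s = recorded  # sitting at a threshold to rounding: trust bookkeeping
            else:
                raise RuntimeError(
                    f"shell bookkeeping inconsistent for pair ({i}, {j}): "
                    f"recorded {recorded}, geometric {s}"
                )
    if s == 0 and math.isinf(potential.energies[0]):
        raise ValueError(f"pair ({i}, {j}) is inside the hard core")
    a = float(v @ v)
    if a == 0.0:
        return None
    b = float(r @ v)
    c = float(r @ r)
    K = len(potential.thresholds)
    best_t = math.inf
    best_dir = 0
    if s < K:
        d = potential.thresholds[s]
        q = min(c - d * d, 0.0)
        t_out = (-b + math.sqrt(b * b - a * q)) / a
        if t_out >= 0:
            best_t, best_dir = t_out, 1
    if s > 0 and b < 0:
        d = potential.thresholds[s - 1]
        q = max(c - d * d, 0.0)
        disc = b * b - a * q
        if disc > _kernels.GRAZE_EPS:
            t_in = (-b - math.sqrt(disc)) / a
            if 0 <= t_in < best_t:
                best_t, best_dir = t_in, -1
    if best_dir == 0:
        return None
    kind = "shell_crossing"
    return Event(time=state.time + best_t, kind=kind, i=i, j=j, direction=best_dir)


def resolve_collision(
    state: SystemState, event: Event, potential: StepPotential
) -> float:
    """Apply a pair event in place; returns the potential-energy change.

    The relative velocity is decomposed along the line of centers; only the
    radial component changes, so angular momentum about the pair's center of
    mass is conserved.  A crossing happens when the radial kinetic energy
    exceeds the step height, otherwise the pair reflects.
    """
    i, j = event.i, event.j
    r, v = _pair_geometry(state, (i, j))
    dist = float(np.linalg.norm(r))
    u = r / dist
    vr = float(v @ u)
    mi, mj = state.masses[i], state.masses[j]
    mu = mi * mj / (mi + mj)
    s = potential.shell_of(dist - 1e-9 * event.direction)  # shell being left
    s_new = s + event.direction
    u_new = potential.energies[s_new] if 0 <= s_new < potential.n_shells else math.inf
    u_cur = potential.energies[s]
    d_pe = 0.0
    if math.isinf(u_new):
        vr_new = -vr
    else:
        dU = u_new - u_cur
        if dU > 0 and 0.5 * mu * vr * vr <= dU:
            vr_new = -vr
        else:
            root = math.sqrt(vr * vr - 2.0 * dU / mu)
            vr_new = root if vr >= 0 else -root
            d_pe = dU
            if state.shells is not None:
                state.shells[pair_index(i, j, state.n_beads)] = s_new
    dv = vr_new - vr
    state.velocities[i] += (mu / mi) * dv * u
    state.velocities[j] -= (mu / mj) * dv * u
    state.potential_energy += d_pe
    return d_pe


def andersen_kick(
    state: SystemState,
    bead: int,
    temperature: float,
    rng: np.random.Generator,
) -> None:
    """Redraw one bead's velocity from the Maxwell–Boltzmann distribution."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    sig = math.sqrt(temperature / state.masses[bead])
    state.velocities[bead] = rng.normal(size=3) * sig


def _pair_maps(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    P = n * (n - 1) // 2
    pi = np.empty(P, dtype=np.int64)
    pj = np.empty(P, dtype=np.int64)
    p = 0
    for i in range(n):
        for j in range(i + 1, n):
            pi[p] = i
            pj[p] = j
            p += 1
    bead_pairs = np.empty((n, n - 1), dtype=np.int64)
    for b in range(n):
        k = 0
        for other in range(n):
            if other != b:
                bead_pairs[b, k] = pair_index(b, other, n)
                k += 1
    return pi, pj, bead_pairs


_PAIR_MAP_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def run(
    state: SystemState,
    model: InteractionModel,
    temperature: float,
    n_timesteps: float,
    thermostat_rate: float = 0.1,
    frame_interval: float = 50.0,
    seed: int = 0,
    collect_events: int = 0,
    window: float = 2.0,
) -> Trajectory:
    """Advance ``state`` in place for ``n_timesteps`` time units.

    Frames (positions, PE, KE) are recorded every ``frame_interval`` t.u.
    starting at the current instant.  With ``thermostat_rate == 0`` the
    dynamics is microcanonical and total energy is conserved to float
    precision per event.  ``window`` is the event-scheduling look-ahead in
    t.u. (a pure performance knob; it must not change the dynamics).
    Deterministic given ``seed``.
    """
    if n_timesteps <= 0:
        raise ValueError("n_timesteps must be positive")
    if state.shells is None:
        state.bind_model(model)
    if not math.isfinite(state.potential_energy):
        raise ValueError(
            "state has non-finite potential energy (hard-core overlap?)"
        )
    n = state.n_beads
    if n not in _PAIR_MAP_CACHE:
        _PAIR_MAP_CACHE[n] = _pair_maps(n)
    pi, pj, bead_pairs = _PAIR_MAP_CACHE[n]
    offsets, nthr, confin, thr, en = model.packed()

    t0 = state.time
    (
        f_t,
        f_pos,
        f_pe,
        f_ke,
        n_events,
        err,
        ev_t,
        ev_kind,
        ev_i,
        ev_j,
        pe,
        ke,
    ) = _kernels.run_kernel(
        state.positions,
        state.velocities,
        state.masses,
        pi,
        pj,
        bead_pairs,
        offsets,
        nthr,
        confin,
        thr,
        en,
        state.shells,
        state.potential_energy,
        float(n_timesteps),
        float(frame_interval),
        float(temperature),
        float(thermostat_rate),
        int(seed) % (2**32),
        int(collect_events),
        float(window),
    )
    if err == _kernels.ERR_HEAP_FULL:
        raise RuntimeError("event queue overflow (heap full after compaction)")
    if n_events == 0 and thermostat_rate == 0.0:
        warnings.warn(
            "no events occurred and the thermostat is off; "
            "system drifted freely to the horizon",
            RuntimeWarning,
        )
    state.time = t0 + float(n_timesteps)
    state.potential_energy = float(pe)

    events = [
        Event(time=t0 + ev_t[k], kind=EVENT_KINDS[ev_kind[k]], i=int(ev_i[k]), j=int(ev_j[k]))
        for k in range(len(ev_t))
    ]
    return Trajectory(
        times=f_t + t0,
        positions=f_pos,
        potential_energy=f_pe,
        kinetic_energy=f_ke,
        temperature=temperature,
        seed=seed,
        n_events=int(n_events),
        events=events,
    )
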