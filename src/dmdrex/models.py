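"""Synthetic model builders: the coarse-grained Gō-like helix bundle and
exactly-distributed synthetic ensembles for stage-isolated testing.

``build_mini_bundle`` produces an idealized four-helix-bundle conformation
(canonical α-helix Cα geometry: 1.5 Å rise, 100° turn, 2.3 Å radius;
antiparallel helices on a 10 Å square grid; hinge and tail extended) and a
Gō-style step-potential table: covalent neighbours sit in narrow confining
wells, pairs in contact in the idealized structure get a single attractive
well, and everything else is hard-core repulsive.

``generate_energy_series`` and ``generate_rc_samples`` draw directly from
the exact Boltzmann distribution of small named systems (no dynamics), so
downstream WHAM and PMF code can be tested against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import SystemState
from .potentials import InteractionModel, StepPotential
from .topology import ChainTopology

__all__ = [
    "GoParameterSet",
    "SyntheticEnsembleSpec",
    "build_mini_bundle",
    "generate_energy_series",
    "generate_rc_samples",
]

RISE = 1.5  # Å per bead along the helix axis
TURN = math.radians(100.0)  # rotation per bead
HELIX_RADIUS = 2.3  # Å, Cα cylinder radius
AXIS_SPACING = 10.0  # Å between neighbouring helix axes
ZIG_STEP = 3.8 * math.sin(math.radians(60.0))  # extended-chain axial step
ZIG_OFF = 3.8 * math.cos(math.radians(60.0))  # alternating lateral offset


@dataclass(frozen=True)
class GoParameterSet:
    """Parameters of the structure-based (Gō) interaction table.

    native_contact_cutoff : Å — pairs closer than this in the idealized
        structure (sequence separation ≥ 3) become attractive.
    well_width : Å — the attractive well extends to the native distance
        plus this width.
    native_well_depth : kcal/mol — depth of each native-contact well.
    nonnative_core_only : all other pairs interact only through the hard
        core (the only supported mode).
    bond_tolerance : half-width of the covalent bond well as a fraction of
        the bond length.
    """

    native_contact_cutoff: float = 7.5
    well_width: float = 1.5
    native_well_depth: float = 1.0
    nonnative_core_only: bool = True
    bond_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.native_well_depth < 0:
            raise ValueError("well depth must be non-negative")
        if self.well_width <= 0:
            raise ValueError("well width must be positive")
        if not (0 < self.bond_tolerance < 1):
            raise ValueError("bond tolerance must lie in (0, 1)")
        if not self.nonnative_core_only:
            raise ValueError(
                "only hard-core non-native interactions are supported"
            )


def _helix_points(length: int, center: np.ndarray, up: bool, phase: float) -> np.ndarray:
    """Beads of one idealized right-handed α-helix around a vertical axis.

    For a helix running downward the rotation sense is reversed so the
    handedness stays right-handed along the chain direction.
    """
    k = np.arange(length)
    ang = phase - (k if up else -k) * TURN
    z = k * RISE if up else (length - 1 - k) * RISE
    return np.column_stack(
        [
            center[0] + HELIX_RADIUS * np.cos(ang),
            center[1] + HELIX_RADIUS * np.sin(ang),
            z,
        ]
    )


def _zigzag_points(length: int, start: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Planar extended (zig-zag) chain continuing from ``start``.

    The first returned bead is one bond away from ``start``.
    """
    u = direction / np.linalg.norm(direction)
    # any unit vector orthogonal to u
    trial = np.array([0.0, 0.0, 1.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, trial)
    p /= np.linalg.norm(p)
    out = np.empty((length, 3))
    for m in range(1, length + 1):
        out[m - 1] = start + u * (m * ZIG_STEP) + p * ((m % 2) * ZIG_OFF)
    return out


def _idealized_geometry(topology: ChainTopology) -> np.ndarray:
    """Idealized bundle conformation for an arbitrary segment layout."""
    s = AXIS_SPACING
    slots = [np.array([0.0, 0.0]), np.array([s, 0.0]), np.array([s, s]), np.array([0.0, s])]
    # phases chosen so junction-facing terminal beads lean into the gaps
    phases = [
        math.radians(0.0),
        math.radians(180.0),
        math.radians(270.0),
        math.radians(0.0),
    ]
    pos = np.zeros((topology.n_beads, 3))
    helix_count = 0
    prev_end: np.ndarray | None = None
    centroid_parts: list[np.ndarray] = []
    for label, start, end in topology.segments:
        idx = np.arange(start - 1, end)
        length = len(idx)
        if label.startswith("H"):
            if length < 4:
                raise ValueError(
                    f"segment {label} has {length} beads; a helix needs at least 4"
                )
            up = helix_count % 2 == 0
            center = slots[helix_count % 4]
            # shift the phase so the first placed bead is the N-side one
            base = phases[helix_count % 4] - (length - 1) * TURN * (0 if up else 1)
            pts = _helix_points(length, center, up, base)
            helix_count += 1
        else:
            if prev_end is None:
                anchor = np.zeros(3)
                direction = np.array([-1.0, 0.0, 0.0])
                pts = _zigzag_points(length, anchor, direction)
            else:
                if centroid_parts:
                    centroid = np.concatenate(centroid_parts).mean(axis=0)
                else:
                    centroid = prev_end + np.array([1.0, 0.0, 0.0])
                direction = prev_end - centroid
                if np.linalg.norm(direction) < 1e-9:
                    direction = np.array([1.0, 0.0, 0.0])
                pts = _zigzag_points(length, prev_end, direction)
        pos[idx] = pts
        prev_end = pts[-1]
        centroid_parts.append(pts)
    return pos


def build_mini_bundle(
    topology: ChainTopology,
    params: GoParameterSet | None = None,
    seed: int = 0,
) -> tuple[InteractionModel, SystemState]:
    """Build the idealized helix-bundle state and its Gō interaction table.

    Native contacts are pairs with sequence separation ≥ 3 that lie within
    ``params.native_contact_cutoff`` in the idealized geometry; each gets a
    single attractive square well ``[hard_core, d_native + well_width]`` of
    depth ``native_well_depth``.  Covalent neighbours are confined to a well
    of ``±bond_tolerance`` around the bond length (junction neighbours whose
    idealized distance falls outside that well are confined around their
    idealized distance instead).  A tiny seeded jitter (10⁻³ Å) breaks exact
    geometric degeneracies; the construction is deterministic given ``seed``.
    """
    params = params or GoParameterSet()
    if params.native_contact_cutoff <= topology.hard_core_diameter:
        raise ValueError("native-contact cutoff must exceed the hard core")

    pos = _idealized_geometry(topology)
    rng = np.random.default_rng(seed)
    pos = pos + rng.normal(scale=1e-3, size=pos.shape)

    n = topology.n_beads
    model = InteractionModel(
        n_beads=n,
        default=StepPotential.hard_core(topology.hard_core_diameter),
    )

    # covalent bonds
    for i in range(n - 1):
        d = float(np.linalg.norm(pos[i + 1] - pos[i]))
        rest = topology.bond_length
        if abs(d - rest) > params.bond_tolerance * rest:
            rest = d  # helix-helix junction: confine around the built length
        model.set_pair(i, i + 1, StepPotential.bond(rest, params.bond_tolerance), "bond")

    # native contacts
    core = topology.hard_core_diameter
    for i in range(n):
        for j in range(i + 3, n):
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d <= params.native_contact_cutoff:
                if d <= core:
                    raise ValueError(
                        f"idealized geometry places pair ({i + 1}, {j + 1}) "
                        f"inside the hard core ({d:.2f} Å)"
                    )
                model.set_pair(
                    i,
                    j,
                    StepPotential.native_well(core, d + params.well_width, params.native_well_depth),
                    "native",
                )

    state = SystemState(
        positions=pos,
        velocities=np.zeros_like(pos),
        masses=topology.masses,
    )
    state.bind_model(model)
    if np.any(
        [
            math.isinf(model.potential(i, j).energies[s])
            for (i, j), s in _occupied_shells(model, state)
        ]
    ):
        raise ValueError("built geometry violates a hard core")
    return model, state


def _occupied_shells(model: InteractionModel, state: SystemState):
    n = model.n_beads
    p = 0
    for i in range(n):
        for j in range(i + 1, n):
            yield (i, j), int(state.shells[p])
            p += 1


# ---------------------------------------------------------------------------
# exactly-distributed synthetic ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Recipe for per-temperature energy samples with known statistics.

    kind:
      * ``two_level`` — params ``energies=(E0, E1)``, ``degeneracies=(g0, g1)``;
        exact Boltzmann sampling of a two-state system.
      * ``harmonic`` — params ``spring_constant``; potential energy of a 1-D
        harmonic oscillator (mean kBT/2 by equipartition).
      * ``gaussian_series`` — params ``means``, ``variances`` (sequences
        aligned with the temperature ladder); plain Gaussian marginals.
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("two_level", "harmonic", "gaussian_series"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.kind == "two_level":
            g = self.parameters.get("degeneracies", (1, 1))
            if any(gi < 1 for gi in g):
                raise ValueError("degeneracies must be >= 1")
        if self.kind == "gaussian_series":
            if any(v <= 0 for v in self.parameters["variances"]):
                raise ValueError("variances must be positive")


def two_level_stats(energies, degeneracies, temperature: float):
    """Closed-form Boltzmann occupancy and mean energy of a two-level system."""
    e0, e1 = energies
    g0, g1 = degeneracies
    w0 = g0 * math.exp(-(e0 - min(e0, e1)) / temperature)
    w1 = g1 * math.exp(-(e1 - min(e0, e1)) / temperature)
    p1 = w1 / (w0 + w1)
    mean = e0 * (1 - p1) + e1 * p1
    var = (e1 - e0) ** 2 * p1 * (1 - p1)
    return p1, mean, var


def generate_energy_series(
    spec: SyntheticEnsembleSpec, temperatures
) -> dict[float, np.ndarray]:
    """Per-temperature energy series drawn from the exact Boltzmann law.

    No dynamics is involved: two-level samples are Bernoulli draws with the
    analytic occupancy; harmonic samples are (kBT/2)·χ²₁.  Reproducible
    under the spec's seed.
    """
    temps = [float(t) for t in np.atleast_1d(np.asarray(temperatures, dtype=float))]
    rng = np.random.default_rng(spec.seed)
    out: dict[float, np.ndarray] = {}
    for t in temps:
        if spec.kind == "two_level":
            e = spec.parameters.get("energies", (0.0, 1.0))
            g = spec.parameters.get("degeneracies", (1, 1))
            p1, _, _ = two_level_stats(e, g, t)
            hits = rng.random(spec.n_samples) < p1
            out[t] = np.where(hits, e[1], e[0]).astype(float)
        elif spec.kind == "harmonic":
            k = spec.parameters.get("spring_constant", 1.0)
            x = rng.normal(scale=math.sqrt(t / k), size=spec.n_samples)
            out[t] = 0.5 * k * x**2
        else:  # gaussian_series
            idx = temps.index(t)
            mu = spec.parameters["means"][idx]
            var = spec.parameters["variances"][idx]
            out[t] = rng.normal(loc=mu, scale=math.sqrt(var), size=spec.n_samples)
    return out


def generate_rc_samples(density_spec, n: int, seed: int = 0) -> np.ndarray:
    """i.i.d. (rmsd, rg) samples from a 2-D Gaussian mixture.

    ``density_spec`` is a sequence of ``(weight, mean, cov)`` with weights
    summing to 1; rejects negative weights.
    """
    weights = np.array([w for w, _, _ in density_spec], dtype=float)
    if np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    out = np.empty((n, 2))
    for c, (_, mean, cov) in enumerate(density_spec):
        mask = comp == c
        m = int(mask.sum())
        if m:
            out[mask] = rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float), size=m)
    return out
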