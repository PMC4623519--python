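"""Conformer-level analytics for trajectory ensembles.

Everything here operates on raw frame arrays (F, n, 3) plus a
:class:`~dmdrex.topology.ChainTopology`, mirroring the standard analyses
used to characterize helix-bundle unfolding: single-pass leader clustering
with a data-driven cutoff, mean/std pairwise-distance matrices, contact
(salt-bridge) occupancy, end-to-end and inter-segment geometry including
the inter-domain angle θ and dihedral φ, a coarse-grained helicity
assignment, and sphere-point-sampled solvent-accessible surface area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landscape import pairwise_rmsd_matrix
from .topology import ChainTopology

__all__ = [
    "ClusterResult",
    "DistanceMatrixPair",
    "GeometryReport",
    "pairwise_rmsd_cutoff",
    "leader_cluster",
    "leader_cluster_distances",
    "distance_matrix",
    "contact_occupancy",
    "geometry_report",
    "helicity_profile",
    "hydrophobic_sasa",
]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Leader-clustering outcome, clusters sorted by size (then leader)."""

    assignments: np.ndarray  # (F,) cluster id per frame
    leaders: list[int]  # frame index of each cluster's leader
    centroids: list[int]  # member minimizing summed RMSD to co-members
    sizes: list[int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.leaders)

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster)[0]

    def to_tsv(self) -> str:
        lines = ["frame\tcluster\tis_leader\tis_centroid"]
        lead = set(self.leaders)
        cent = set(self.centroids)
        for f, c in enumerate(self.assignments):
            lines.append(f"{f}\t{c}\t{int(f in lead)}\t{int(f in cent)}")
        return "\n".join(lines) + "\n"


def pairwise_rmsd_cutoff(
    frames: np.ndarray,
    selection: np.ndarray | None = None,
    bin_width: float = 1.0,
    dmat: np.ndarray | None = None,
) -> float:
    """Clustering cutoff = center of the modal bin of all pairwise RMSDs.

    Ties pick the lower bin.  All-identical frames give cutoff 0 with a
    warning.
    """
    if dmat is None:
        if len(frames) < 2:
            raise ValueError("need at least two frames")
        dmat = pairwise_rmsd_matrix(frames, selection)
    vals = dmat[np.triu_indices(len(dmat), k=1)]
    if vals.max() < 1e-6:
        warnings.warn("all frames identical; pairwise-RMSD cutoff is 0", RuntimeWarning)
        return 0.0
    nbins = max(1, int(np.ceil(vals.max() / bin_width + 1e-9)))
    edges = bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    modal = int(np.argmax(counts))  # argmax takes the first (lower) bin on ties
    return float(edges[modal] + bin_width / 2)


def leader_cluster_distances(dmat: np.ndarray, cutoff: float) -> ClusterResult:
    """Leader pass over a precomputed symmetric distance matrix.

    Frames are visited in order; a frame joins the FIRST existing leader
    within ``cutoff``, otherwise it founds a new cluster.  Centroids
    minimize the summed distance to co-members (ties: lowest frame index).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    F = len(dmat)
    raw = -np.ones(F, dtype=int)
    leaders: list[int] = []
    for f in range(F):
        for c, lead in enumerate(leaders):
            if dmat[f, lead] <= cutoff:
                raw[f] = c
                break
        else:
            raw[f] = len(leaders)
            leaders.append(f)
    sizes = np.bincount(raw, minlength=len(leaders))
    order = sorted(range(len(leaders)), key=lambda c: (-sizes[c], leaders[c]))
    relabel = {old: new for new, old in enumerate(order)}
    assignments = np.array([relabel[c] for c in raw])
    leaders_sorted = [leaders[c] for c in order]
    centroids = []
    for new in range(len(order)):
        mem = np.nonzero(assignments == new)[0]
        summed = dmat[np.ix_(mem, mem)].sum(axis=1)
        centroids.append(int(mem[int(np.argmin(summed))]))
    return ClusterResult(
        assignments=assignments,
        leaders=leaders_sorted,
        centroids=centroids,
        sizes=[int(sizes[c]) for c in order],
        cutoff=float(cutoff),
    )


def leader_cluster(
    frames: np.ndarray,
    selection: np.ndarray | None = None,
    cutoff: float | None = None,
    bin_width: float = 1.0,
) -> ClusterResult:
    """Leader clustering of frames by superposed RMSD.

    With ``cutoff=None`` the cutoff is taken from the modal bin of the
    pairwise-RMSD distribution (the data-driven rule).
    """
    dmat = pairwise_rmsd_matrix(frames, selection)
    if cutoff is None:
        cutoff = pairwise_rmsd_cutoff(frames, selection, bin_width, dmat=dmat)
    return leader_cluster_distances(dmat, cutoff)


# ---------------------------------------------------------------------------
# distance matrices and contacts
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrixPair:
    """n×n matrix: upper triangle = ensemble mean pair distance (Å),
    lower triangle = its standard deviation, diagonal 0."""

    matrix: np.ndarray
    mode: str = "ca"

    def mean(self, i: int, j: int) -> float:
        return float(self.matrix[min(i, j), max(i, j)])

    def std(self, i: int, j: int) -> float:
        return float(self.matrix[max(i, j), min(i, j)])

    def to_tsv(self) -> str:
        return (
            "\n".join("\t".join(f"{v:.4f}" for v in row) for row in self.matrix)
            + "\n"
        )


def distance_matrix(frames: np.ndarray, mode: str = "ca") -> DistanceMatrixPair:
    """Mean/std pairwise-distance matrix over an ensemble of frames.

    Mode ``ca`` measures bead(Cα) distances; ``sidechain_centroid`` would
    need side-chain atoms, which the coarse-grained model does not carry.
    """
    if mode == "sidechain_centroid":
        raise ValueError(
            "sidechain_centroid distances need side-chain atoms; "
            "the Cα-bead model only supports mode='ca'"
        )
    if mode != "ca":
        raise ValueError(f"unknown distance mode {mode!r}")
    x = np.asarray(frames, dtype=float)
    if x.ndim != 3 or len(x) < 1:
        raise ValueError("frames must be a nonempty (F, n, 3) array")
    diff = x[:, :, None, :] - x[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))  # (F, n, n)
    mean = d.mean(axis=0)
    std = d.std(axis=0)
    n = mean.shape[0]
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = mean[iu]
    out[iu[1], iu[0]] = std[iu]
    return DistanceMatrixPair(matrix=out, mode="ca")


@dataclass
class ContactReport:
    pairs: list[tuple[int, int]]
    occupancy: np.ndarray  # fraction of frames with distance ≤ threshold
    threshold: float
    histograms: list[tuple[np.ndarray, np.ndarray]]  # (counts, edges) per pair


def contact_occupancy(
    frames: np.ndarray,
    pairs: list[tuple[int, int]],
    threshold: float,
    bin_width: float = 1.0,
) -> ContactReport:
    """Fraction of frames in which each pair is within ``threshold`` Å,
    plus per-pair distance histograms on 1 Å bins."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(frames, dtype=float)
    occ = np.empty(len(pairs))
    hists = []
    for k, (i, j) in enumerate(pairs):
        d = np.linalg.norm(x[:, i] - x[:, j], axis=1)
        occ[k] = float(np.mean(d <= threshold))
        nb = max(1, int(np.ceil(d.max() / bin_width + 1e-9)))
        edges = bin_width * np.arange(nb + 1)
        hists.append((np.histogram(d, bins=edges)[0], edges))
    return ContactReport(
        pairs=list(pairs), occupancy=occ, threshold=threshold, histograms=hists
    )


# ---------------------------------------------------------------------------
# geometry: end-to-end, segment COM distances, θ and φ
# ---------------------------------------------------------------------------


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, degrees, in [0, 180]."""
    u = a - b
    v = c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def axis_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral φ between axis vectors p1→p2 and p3→p4, degrees.

    Orientation convention: 0° means the two axes are antiparallel and
    ±180° parallel (the N→C direction of each axis sets the sign).
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m @ n2
    # the standard four-point dihedral of (p1, p2, p3, p4) realizes the
    # convention directly: antiparallel axes -> 0, parallel -> ±180
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class GeometryReport:
    """Distance/angle series characterizing the inter-domain arrangement."""

    end_to_end: np.ndarray  # Å, first vs last bead
    segment_com_distances: dict[str, np.ndarray]  # vs helix-4 COM, Å
    theta: np.ndarray  # degrees, [0, 180]
    phi: np.ndarray  # degrees, (−180, 180]
    bin_width: float = 1.0

    def histogram(self, series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.floor(series.min() / self.bin_width) * self.bin_width
        nb = max(1, int(np.ceil((series.max() - lo) / self.bin_width + 1e-9)))
        edges = lo + self.bin_width * np.arange(nb + 1)
        return np.histogram(series, bins=edges)


def geometry_report(frames: np.ndarray, topology: ChainTopology) -> GeometryReport:
    """End-to-end, segment-COM, θ and φ series for a trajectory.

    θ uses three anchors — a bead two-thirds along helix 4, the helix-4
    C-terminal bead (vertex), and the tail's central bead — mirroring the
    use of the most stable helix as the N-domain reference and the tail
    center as the C-domain reference.  φ is the signed dihedral between
    the helix-4 axis and the tail axis (each taken N→C).
    """
    x = np.asarray(frames, dtype=float)
    for needed in ("H4", "tail"):
        try:
            topology.segment(needed)
        except KeyError as exc:
            raise ValueError(f"topology lacks segment {needed!r} required for geometry") from exc
    h4 = topology.segment_indices("H4")
    tail = topology.segment_indices("tail")

    end_to_end = np.linalg.norm(x[:, -1] - x[:, 0], axis=1)

    h4_com = x[:, h4].mean(axis=1)
    com_dist = {}
    for label, _, _ in topology.segments:
        if label == "H4":
            continue
        seg = topology.segment_indices(label)
        com_dist[label] = np.linalg.norm(x[:, seg].mean(axis=1) - h4_com, axis=1)

    a_idx = h4[(2 * len(h4)) // 3]
    b_idx = h4[-1]
    c_idx = tail[len(tail) // 2]
    theta = np.array([bond_angle(f[a_idx], f[b_idx], f[c_idx]) for f in x])
    phi = np.array(
        [axis_dihedral(f[h4[0]], f[h4[-1]], f[tail[0]], f[tail[-1]]) for f in x]
    )
    return GeometryReport(
        end_to_end=end_to_end,
        segment_com_distances=com_dist,
        theta=theta,
        phi=phi,
    )


# ---------------------------------------------------------------------------
# helicity
# ---------------------------------------------------------------------------

HELIX_DIHEDRAL = (30.0, 70.0)  # virtual Cα dihedral window, degrees
HELIX_ANGLE = (75.0, 115.0)  # virtual bond-angle window, degrees
EXTENDED_DIHEDRAL = 150.0  # |dihedral| beyond this counts as extended


def _virtual_dihedral(p1, p2, p3, p4) -> float:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return 180.0  # collinear stretch: treat as fully extended
    m = np.cross(n1, b2 / nb2)
    return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))


def helicity_profile(
    frames_by_temperature: dict[float, np.ndarray], topology: ChainTopology
) -> dict[float, dict[str, np.ndarray]]:
    """Per-residue helix/strand/loop fractions per temperature.

    A coarse-grained surrogate assignment on Cα virtual geometry (not an
    all-atom secondary-structure algorithm): residue i is H when the
    virtual dihedral of beads (i−1, i, i+1, i+2) lies in the α-helical
    window and both flanking virtual bond angles are canonical; extended
    dihedrals give B; everything else (including chain termini) L.
    """
    if topology.n_beads < 5:
        raise ValueError("helicity needs a chain of at least 5 beads")
    out = {}
    n = topology.n_beads
    for t, frames in frames_by_temperature.items():
        x = np.asarray(frames, dtype=float)
        counts = {k: np.zeros(n) for k in "HBL"}
        for f in x:
            for i in range(1, n - 2):
                dih = _virtual_dihedral(f[i - 1], f[i], f[i + 1], f[i + 2])
                ang1 = bond_angle(f[i - 1], f[i], f[i + 1])
                ang2 = bond_angle(f[i], f[i + 1], f[i + 2])
                helical_angles = (
                    HELIX_ANGLE[0] <= ang1 <= HELIX_ANGLE[1]
                    and HELIX_ANGLE[0] <= ang2 <= HELIX_ANGLE[1]
                )
                if HELIX_DIHEDRAL[0] <= dih <= HELIX_DIHEDRAL[1] and helical_angles:
                    counts["H"][i] += 1
                elif abs(dih) >= EXTENDED_DIHEDRAL:
                    counts["B"][i] += 1
                else:
                    counts["L"][i] += 1
            for i in (0, n - 2, n - 1):
                counts["L"][i] += 1
        total = len(x)
        out[t] = {k: v / total for k, v in counts.items()}
    return out


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def hydrophobic_sasa(
    coords: np.ndarray,
    radii: np.ndarray | float,
    probe_radius: float = 1.4,
    labels: np.ndarray | None = None,
    n_points: int = 960,
) -> float:
    """Solvent-accessible surface area (Å²) summed over labelled beads.

    Numerical sphere-point sampling with a fixed quasi-uniform (Fibonacci)
    point set: a point on bead i's expanded sphere (r_i + probe) counts as
    accessible when inside no other expanded sphere.  ``labels`` masks the
    beads included in the sum (default: all — pass the hydrophobic set).
    """
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    r = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    if np.any(r <= 0):
        raise ValueError("bead radii must be positive")
    mask = np.ones(n, dtype=bool) if labels is None else np.asarray(labels, dtype=bool)
    sphere = _fibonacci_sphere(n_points)
    expanded = r + probe_radius
    total = 0.0
    for i in np.nonzero(mask)[0]:
        pts = x[i] + expanded[i] * sphere
        buried = np.zeros(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = ((pts - x[j]) ** 2).sum(axis=1)
            buried |= d2 < expanded[j] ** 2
            if buried.all():
                break
        frac = 1.0 - buried.mean()
        total += frac * 4.0 * np.pi * expanded[i] ** 2
    return float(total)
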