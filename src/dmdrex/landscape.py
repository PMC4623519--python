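"""Reaction coordinates and potential-of-mean-force landscapes.

The conformational state of the bundle is projected onto two collective
variables: the RMSD from a reference structure and the radius of gyration,
both over the Cα beads of the four helices (the flexible hinge/tail is
excluded to reduce state degeneracy).  The PMF over the 2-D histogram W is

    PMF(RMSD, Rg) = −kB T ln W(RMSD, Rg) + C

with C fixing the lowest occupied bin to zero; the partition-function term
of the underlying Helmholtz free energy is absorbed into C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .wham import CvCurve

__all__ = [
    "ReactionCoordinateSeries",
    "FreeEnergySurface",
    "superpose_rmsd",
    "radius_of_gyration",
    "coordinate_series",
    "compute_pmf",
    "assign_state_temperatures",
    "extract_basin",
    "rmsd_to_centroids",
]


def superpose_rmsd(
    coords: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> float:
    """Minimum RMSD (Å) after optimal rigid superposition.

    Centroids are removed and the optimal proper rotation is found by
    least squares (no reflections), so the result is invariant under rigid
    motion of either structure.
    """
    a = np.asarray(coords, dtype=float)
    b = np.asarray(reference, dtype=float)
    if selection is not None:
        a = a[selection]
        b = b[selection]
    if a.shape != b.shape:
        raise ValueError("selections must have identical sizes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    diff = a - rot.apply(b)
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def pairwise_rmsd_matrix(
    frames: np.ndarray, selection: np.ndarray | None = None
) -> np.ndarray:
    """All-against-all superposed RMSD, via batched 3×3 SVDs.

    ``frames`` has shape (F, n, 3); returns an (F, F) symmetric matrix.
    """
    x = np.asarray(frames, dtype=float)
    if selection is not None:
        x = x[:, selection]
    F, n, _ = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", x, x)
    ii, jj = np.triu_indices(F, k=1)
    # cross-covariance for every pair, then the Kabsch trace with the
    # proper-rotation sign fix
    H = np.einsum("pik,pil->pkl", x[ii], x[jj])
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", U, Vt)))
    trace = S[:, 0] + S[:, 1] + sign * S[:, 2]
    msd = (sq[ii] + sq[jj] - 2.0 * trace) / n
    out = np.zeros((F, F))
    out[ii, jj] = out[jj, ii] = np.sqrt(np.maximum(msd, 0.0))
    return out


def radius_of_gyration(
    coords: np.ndarray,
    selection: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration, Å."""
    x = np.asarray(coords, dtype=float)
    if selection is not None:
        x = x[selection]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    if masses is None:
        m = np.ones(x.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if selection is not None and m.shape[0] != x.shape[0]:
            m = m[selection]
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * x).sum(axis=0) / total
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / total))


@dataclass
class ReactionCoordinateSeries:
    """Per-frame (RMSD, Rg) for a fixed selection and reference."""

    rmsd: np.ndarray
    rg: np.ndarray
    temperature: float = np.nan
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.rmsd < 0) or np.any(self.rg <= 0):
            raise ValueError("rmsd must be ≥ 0 and rg > 0")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.rmsd, self.rg])


def coordinate_series(
    frames: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
    masses: np.ndarray | None = None,
    temperature: float = np.nan,
) -> ReactionCoordinateSeries:
    """(RMSD, Rg) series for a trajectory against a reference structure."""
    rmsd = np.array([superpose_rmsd(f, reference, selection) for f in frames])
    rg = np.array([radius_of_gyration(f, selection, masses) for f in frames])
    return ReactionCoordinateSeries(rmsd=rmsd, rg=rg, temperature=temperature)


@dataclass
class FreeEnergySurface:
    """PMF over (RMSD, Rg) bins; empty bins are masked, not zero."""

    rmsd_edges: np.ndarray
    rg_edges: np.ndarray
    pmf: np.ndarray  # (n_rmsd, n_rg), kcal/mol; NaN on empty bins
    temperature: float
    counts: np.ndarray | None = None

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.pmf)

    def to_tsv(self) -> str:
        lines = [
            "# rmsd_edges\t" + "\t".join(f"{e:.6g}" for e in self.rmsd_edges),
            "# rg_edges\t" + "\t".join(f"{e:.6g}" for e in self.rg_edges),
        ]
        for row in self.pmf:
            lines.append(
                "\t".join("NA" if not np.isfinite(v) else f"{v:.6g}" for v in row)
            )
        return "\n".join(lines) + "\n"


def compute_pmf(
    series: ReactionCoordinateSeries,
    bin_width: tuple[float, float] = (1.0, 1.0),
    temperature: float | None = None,
) -> FreeEnergySurface:
    """PMF(RMSD, Rg) = −kBT ln W + C on a uniform 2-D grid.

    W is the normalized occupancy histogram; C shifts the occupied-bin
    minimum to zero, so doubling all counts leaves the surface unchanged.
    Temperature is reduced (kBT in kcal/mol).
    """
    t = series.temperature if temperature is None else temperature
    if not np.isfinite(t) or t <= 0:
        raise ValueError("a positive temperature is required")
    wr, wg = bin_width
    r_lo = np.floor(series.rmsd.min() / wr) * wr
    g_lo = np.floor(series.rg.min() / wg) * wg
    nr = max(1, int(np.ceil((series.rmsd.max() - r_lo) / wr + 1e-9)))
    ng = max(1, int(np.ceil((series.rg.max() - g_lo) / wg + 1e-9)))
    r_edges = r_lo + wr * np.arange(nr + 1)
    g_edges = g_lo + wg * np.arange(ng + 1)
    counts, _, _ = np.histogram2d(series.rmsd, series.rg, bins=(r_edges, g_edges))
    w = counts / counts.sum()
    with np.errstate(divide="ignore"):
        pmf = -t * np.log(w)
    pmf[counts == 0] = np.nan
    pmf -= np.nanmin(pmf)
    return FreeEnergySurface(
        rmsd_edges=r_edges, rg_edges=g_edges, pmf=pmf, temperature=t, counts=counts
    )


def assign_state_temperatures(cv: CvCurve, n_states: int = 4) -> dict[str, float]:
    """Label the conformational-state temperatures T1..Tn from a Cv curve.

    T1 is the lowest analysis temperature; subsequent labels are the local
    minima bracketed by successive Cv peaks (T2 below the first peak when a
    minimum exists there, T3 between first and second peaks, the last label
    the final minimum).  A monotone curve yields T1 only.
    """
    out = {"T1": float(cv.temperatures[0])}
    minima = [float(m) for m in cv.minima]
    if not len(cv.peaks) or not minima:
        return out
    peaks = [float(p) for p in cv.peaks]
    label = 2
    # minima below the first peak
    below = [m for m in minima if m < peaks[0]]
    if below and label <= n_states:
        out[f"T{label}"] = below[-1]
        label += 1
    # minima between successive peaks, then after the last peak
    brackets = list(zip(peaks, peaks[1:])) + [(peaks[-1], np.inf)]
    for lo, hi in brackets:
        if label > n_states:
            break
        inside = [m for m in minima if lo < m < hi]
        if inside:
            out[f"T{label}"] = inside[0] if np.isfinite(hi) else inside[-1]
            label += 1
    return out


def extract_basin(
    series: ReactionCoordinateSeries,
    surface: FreeEnergySurface,
    depth_cutoff: float = 1.0,
) -> np.ndarray:
    """Frame indices of the lowest free-energy basin.

    The basin is the 4-connected component of occupied bins with
    PMF ≤ ``depth_cutoff`` that contains the global minimum bin.
    """
    low = np.where(np.isfinite(surface.pmf), surface.pmf <= depth_cutoff, False)
    labels, _ = ndimage.label(low, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    min_bin = np.unravel_index(np.nanargmin(surface.pmf), surface.pmf.shape)
    basin_label = labels[min_bin]
    ri = np.clip(
        np.digitize(series.rmsd, surface.rmsd_edges) - 1, 0, surface.pmf.shape[0] - 1
    )
    gi = np.clip(
        np.digitize(series.rg, surface.rg_edges) - 1, 0, surface.pmf.shape[1] - 1
    )
    return np.nonzero(labels[ri, gi] == basin_label)[0]


def rmsd_to_centroids(
    frames: np.ndarray,
    centroids: list[np.ndarray],
    selection: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-frame minimum RMSD to a set of centroid structures.

    Returns the (F, C) RMSD table's row-minimum and the nearest-centroid
    label per frame ("native-like"/"intermediate-like" semantics when two
    centroids are supplied in that order).
    """
    if labels is None:
        if len(centroids) == 2:
            labels = ["native-like", "intermediate-like"]
        else:
            labels = [f"centroid_{k}" for k in range(len(centroids))]
    table = np.column_stack(
        [
            [superpose_rmsd(f, c, selection) for f in frames]
            for c in centroids
        ]
    )
    nearest = table.argmin(axis=1)
    return table.min(axis=1), [labels[k] for k in nearest]
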