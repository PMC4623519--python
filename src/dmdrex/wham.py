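"""WHAM density-of-states reconstruction and heat-capacity analysis.

The weighted histogram analysis method combines potential-energy histograms
collected at several temperatures into one relative density of states
Ω(E), solving self-consistently

    Ω(E) = Σ_k n_k(E) / Σ_k N_k exp(f_k − β_k E)
    f_k  = −ln Σ_E Ω(E) exp(−β_k E) ΔE

by direct substitution in log space.  Canonical averages over Ω give the
heat capacity Cv(T) = (⟨E²⟩ − ⟨E⟩²)/(kB T²), reported in units of kB;
peaks mark cooperative transitions and local minima metastable states.
Uncertainty bands come from a block bootstrap over contiguous trajectory
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy import stats

from .units import KB

__all__ = [
    "EnergyHistogramSet",
    "WhamResult",
    "CvCurve",
    "wham_solve",
    "heat_capacity",
    "cv_uncertainty",
    "convergence_windows",
    "energy_normality",
    "discard_equilibration",
]

DEFAULT_BIN_WIDTH = 1.0  # kcal/mol
CV_GRID_STEP = 0.002  # reduced temperature, ≡ 1 K


@dataclass
class EnergyHistogramSet:
    """Shared-bin energy histograms for a set of temperatures."""

    bin_edges: np.ndarray  # (M+1,) kcal/mol, uniform
    counts: np.ndarray  # (K, M)
    temperatures: np.ndarray  # (K,) reduced

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if self.counts.shape != (len(self.temperatures), len(self.bin_edges) - 1):
            raise ValueError("counts shape mismatch")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("every temperature needs a nonempty histogram")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @staticmethod
    def from_series(
        series: dict[float, np.ndarray], bin_width: float = DEFAULT_BIN_WIDTH
    ) -> "EnergyHistogramSet":
        """Histogram per-temperature energy samples on a shared uniform grid."""
        temps = np.array(sorted(series), dtype=float)
        lo = min(float(np.min(series[t])) for t in temps)
        hi = max(float(np.max(series[t])) for t in temps)
        start = np.floor(lo / bin_width) * bin_width
        nbins = max(1, int(np.ceil((hi - start) / bin_width + 1e-9)))
        edges = start + bin_width * np.arange(nbins + 1)
        counts = np.stack(
            [np.histogram(series[t], bins=edges)[0] for t in temps]
        ).astype(float)
        return EnergyHistogramSet(edges, counts, temps)


@dataclass
class WhamResult:
    """Relative density of states and per-temperature free energies."""

    log_omega: np.ndarray  # (M,), −inf on empty bins; max is 0 (Ω_max = 1)
    free_energies: np.ndarray  # (K,) dimensionless f_k
    bin_centers: np.ndarray
    bin_width: float
    temperatures: np.ndarray
    n_iterations: int
    residual: float

    @property
    def omega(self) -> np.ndarray:
        return np.exp(self.log_omega)


def _connectivity_report(hists: EnergyHistogramSet) -> list[set[int]]:
    """Group temperatures into islands connected by shared occupied bins."""
    K = len(hists.temperatures)
    occupied = [set(np.nonzero(hists.counts[k])[0]) for k in range(K)]
    islands: list[set[int]] = []
    for k in range(K):
        merged = {k}
        bins = set(occupied[k])
        rest = []
        for isl_ks, isl_bins in islands:
            if bins & isl_bins:
                merged |= isl_ks
                bins |= isl_bins
            else:
                rest.append((isl_ks, isl_bins))
        islands = rest + [(merged, bins)]
    return [ks for ks, _ in islands]


def wham_solve(
    hists: EnergyHistogramSet, tol: float = 1e-7, max_iter: int = 100_000
) -> WhamResult:
    """Self-consistent WHAM solution by direct log-space substitution.

    Iterates until max_k |Δf_k| < tol; raises on non-convergence (the
    error carries the residual).  Non-overlapping histogram islands only
    produce a warning — the relative Ω is then undetermined between
    islands.
    """
    islands = _connectivity_report(hists)
    if len(islands) > 1:
        warnings.warn(
            f"energy histograms form {len(islands)} disconnected islands "
            f"{[sorted(i) for i in islands]}; relative Ω between islands "
            "is undetermined",
            RuntimeWarning,
        )
    beta = 1.0 / hists.temperatures  # (K,)
    E = hists.bin_centers  # (M,)
    dE = hists.bin_width
    n_sum = hists.counts.sum(axis=0)  # (M,)
    occupied = n_sum > 0
    log_n_sum = np.where(occupied, np.log(np.maximum(n_sum, 1e-300)), -np.inf)
    log_N = np.log(hists.totals)  # (K,)

    f = np.zeros(len(beta))
    bE = beta[:, None] * E[None, :]  # (K, M)
    resid = np.inf
    for it in range(1, max_iter + 1):
        # log Ω(E) on occupied bins
        denom = logsumexp(log_N[:, None] + f[:, None] - bE, axis=0)  # (M,)
        log_omega = np.where(occupied, log_n_sum - denom, -np.inf)
        with np.errstate(invalid="ignore"):
            f_new = -logsumexp(
                log_omega[None, :] - bE + np.log(dE), axis=1, b=occupied[None, :]
            )
        f_new = f_new - f_new[0]  # gauge: f_0 = 0
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge: residual {resid:.3e} after {max_iter} iterations"
        )
    denom = logsumexp(log_N[:, None] + f[:, None] - bE, axis=0)
    log_omega = np.where(occupied, log_n_sum - denom, -np.inf)
    log_omega = log_omega - np.max(log_omega[occupied])  # Ω_max = 1
    return WhamResult(
        log_omega=log_omega,
        free_energies=f,
        bin_centers=E,
        bin_width=dE,
        temperatures=hists.temperatures,
        n_iterations=it,
        residual=resid,
    )


@dataclass
class CvCurve:
    """Heat capacity vs temperature with extrema annotation.

    ``cv`` is in units of kB; ``temperatures`` reduced (kcal/(mol·kB)),
    with a Kelvin view via kB = 0.002.  ``peaks``/``minima`` are reduced
    temperatures of local extrema of the lightly smoothed curve.
    """

    temperatures: np.ndarray
    cv: np.ndarray
    uncertainty: np.ndarray | None = None
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    minima: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def kelvin(self) -> np.ndarray:
        return self.temperatures / KB

    def to_tsv(self) -> str:
        lines = ["T_reduced\tT_kelvin\tCv_per_kB\tuncertainty"]
        unc = (
            self.uncertainty
            if self.uncertainty is not None
            else np.full_like(self.cv, np.nan)
        )
        for t, c, u in zip(self.temperatures, self.cv, unc):
            lines.append(f"{t:.6g}\t{t / KB:.6g}\t{c:.8g}\t{u:.6g}")
        return "\n".join(lines) + "\n"


def _find_extrema(t_grid: np.ndarray, cv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima/minima after a 3-point moving-average smooth."""
    if len(cv) < 3:
        return np.empty(0), np.empty(0)
    sm = cv.copy()
    sm[1:-1] = (cv[:-2] + cv[1:-1] + cv[2:]) / 3.0
    interior = np.arange(1, len(sm) - 1)
    is_max = (sm[interior] > sm[interior - 1]) & (sm[interior] >= sm[interior + 1])
    is_min = (sm[interior] < sm[interior - 1]) & (sm[interior] <= sm[interior + 1])
    return t_grid[interior[is_max]], t_grid[interior[is_min]]


def canonical_moments(
    result: WhamResult, temperature: float
) -> tuple[float, float]:
    """⟨E⟩ and Var(E) in the canonical ensemble defined by Ω at one T."""
    occ = np.isfinite(result.log_omega)
    logw = result.log_omega[occ] - result.bin_centers[occ] / temperature
    logw = logw - logsumexp(logw)
    w = np.exp(logw)
    e = result.bin_centers[occ]
    mean = float(w @ e)
    var = float(w @ (e - mean) ** 2)
    return mean, var


def heat_capacity(result: WhamResult, t_grid: np.ndarray | None = None) -> CvCurve:
    """Cv(T) from the reconstructed density of states.

    Cv/kB = Var(E)/T² with T reduced and E in kcal/mol.  The default grid
    spans the histogram temperatures in steps equivalent to 1 K.
    """
    if t_grid is None:
        t_grid = np.arange(
            result.temperatures.min(), result.temperatures.max() + CV_GRID_STEP / 2,
            CV_GRID_STEP,
        )
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise ValueError("temperatures must be positive")
    cv = np.empty_like(t_grid)
    for k, t in enumerate(t_grid):
        _, var = canonical_moments(result, t)
        cv[k] = var / t**2
    peaks, minima = _find_extrema(t_grid, cv)
    return CvCurve(temperatures=t_grid, cv=cv, peaks=peaks, minima=minima)


def cv_uncertainty(
    series: dict[float, np.ndarray],
    n_blocks: int = 20,
    n_bootstrap: int = 20,
    bin_width: float = DEFAULT_BIN_WIDTH,
    t_grid: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-bootstrap uncertainty band for the Cv curve.

    Each replicate resamples ``n_blocks`` contiguous blocks per
    temperature with replacement, reruns WHAM and recomputes Cv; the band
    is the standard deviation across replicates.  Returns (t_grid, band).
    Deterministic under ``seed``.
    """
    if n_blocks < 4:
        raise ValueError("need at least 4 blocks")
    lengths = {t: len(v) for t, v in series.items()}
    if min(lengths.values()) < n_blocks:
        raise ValueError("too few samples per temperature for the block count")
    rng = np.random.default_rng(seed)
    blocks = {
        t: np.array_split(np.asarray(v, dtype=float), n_blocks)
        for t, v in series.items()
    }
    if t_grid is None:
        temps = np.array(sorted(series))
        t_grid = np.arange(temps.min(), temps.max() + CV_GRID_STEP / 2, CV_GRID_STEP)
    curves = np.empty((n_bootstrap, len(t_grid)))
    for b in range(n_bootstrap):
        resampled = {}
        for t, blks in blocks.items():
            pick = rng.integers(0, n_blocks, size=n_blocks)
            resampled[t] = np.concatenate([blks[p] for p in pick])
        hists = EnergyHistogramSet.from_series(resampled, bin_width)
        curves[b] = heat_capacity(wham_solve(hists, tol=tol), t_grid).cv
    return t_grid, curves.std(axis=0)


def convergence_windows(
    series: dict[float, np.ndarray],
    window_length: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    t_grid: np.ndarray | None = None,
) -> tuple[list[CvCurve], np.ndarray]:
    """Cv curve per consecutive trajectory window plus first-peak drift.

    ``window_length`` counts samples per temperature.  Returns the per-
    window curves and the array of first-peak temperatures (NaN when a
    window has no peak).
    """
    n = min(len(v) for v in series.values())
    if window_length > n:
        raise ValueError("window longer than the shortest series")
    n_windows = n // window_length
    curves = []
    first_peaks = []
    for w in range(n_windows):
        sl = slice(w * window_length, (w + 1) * window_length)
        sub = {t: np.asarray(v)[sl] for t, v in series.items()}
        cv = heat_capacity(wham_solve(EnergyHistogramSet.from_series(sub, bin_width)), t_grid)
        curves.append(cv)
        first_peaks.append(cv.peaks[0] if len(cv.peaks) else np.nan)
    return curves, np.asarray(first_peaks)


@dataclass(frozen=True)
class NormalityVerdict:
    statistic: float
    p_value: float
    normal: bool
    skewness: float
    excess_kurtosis: float
    histogram: tuple[np.ndarray, np.ndarray]  # counts, edges (1 kcal/mol bins)


def energy_normality(
    samples: np.ndarray, alpha: float = 0.01, bin_width: float = DEFAULT_BIN_WIDTH
) -> NormalityVerdict:
    """Moment-based (skewness/kurtosis omnibus) normality check.

    Validates treating per-temperature energy marginals as Gaussian, the
    premise behind reading the replica set as sampling the partition
    function.  Requires ≥ 100 samples.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    stat, p = stats.normaltest(x)
    lo = np.floor(x.min() / bin_width) * bin_width
    nb = max(1, int(np.ceil((x.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(nb + 1)
    counts, _ = np.histogram(x, bins=edges)
    return NormalityVerdict(
        statistic=float(stat),
        p_value=float(p),
        normal=bool(p > alpha),
        skewness=float(stats.skew(x)),
        excess_kurtosis=float(stats.kurtosis(x)),
        histogram=(counts, edges),
    )


def discard_equilibration(
    energy_series: list[np.ndarray],
    energy_times: list[np.ndarray],
    temperatures,
    fraction: float = 1.0 / 12.0,
) -> dict[float, np.ndarray]:
    """Drop the leading equilibration stretch from per-temperature series.

    ``fraction`` is the portion of the run treated as equilibration (the
    source protocol discards 5×10⁵ of 6×10⁶ steps ≈ 1/12); samples with
    time ≤ fraction × horizon are excluded.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    horizon = max(float(t[-1]) for t in energy_times if len(t))
    cut = fraction * horizon
    out = {}
    for t, e, tim in zip(temperatures, energy_series, energy_times):
        keep = tim > cut
        out[float(t)] = np.asarray(e)[keep]
    return out
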