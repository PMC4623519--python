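"""End-to-end orchestration: build → REX/DMD → WHAM → PMF → clustering →
structural reports, with a serializable configuration and a manifest.

The pipeline mirrors the standard helix-bundle unfolding protocol: a
replica-exchange run over a temperature ladder, WHAM heat capacity on the
post-equilibration energy series, state temperatures T1..T4 from the Cv
extrema, PMF landscapes and basin clustering at those temperatures, and
the conformer-level analytics at each state.  Everything is reproducible
bit-for-bit from the config's seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, landscape, wham
from .models import GoParameterSet, build_mini_bundle
from .pdbio import write_beads_pdb
from .rex import ReplicaEnsemble, build_ladder, replica_mobility, run_rex
from .topology import ChainTopology, mini_bundle_topology
from .units import KB, reduced_to_kelvin, steps_to_ns, kelvin_to_reduced, ns_to_steps

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "convert_temperature", "convert_time"]


def convert_temperature(value: float, to: str = "kelvin") -> float:
    """Convert between reduced temperature and Kelvin (kB = 0.002)."""
    if to == "kelvin":
        return reduced_to_kelvin(value)
    if to == "reduced":
        return kelvin_to_reduced(value)
    raise ValueError("to must be 'kelvin' or 'reduced'")


def convert_time(value: float, to: str = "ns") -> float:
    """Convert between time steps (t.u.) and nanoseconds (2e4 t.u. = 1 ns)."""
    if to == "ns":
        return steps_to_ns(value)
    if to == "steps":
        return ns_to_steps(value)
    raise ValueError("to must be 'ns' or 'steps'")


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one pipeline run.

    Defaults encode the replica-exchange protocol (24 replicas, ladder
    0.35–0.81 in 0.02 steps, analysis over 0.4–0.8, 1/12 of the horizon
    discarded as equilibration) at a desk-scale horizon.
    """

    helix_len: int = 10
    hinge_len: int = 6
    tail_len: int = 10
    ladder_min: float = 0.35
    ladder_max: float = 0.81
    ladder_increment: float = 0.02
    horizon: float = 2.0e5  # t.u.
    equilibration_fraction: float = 1.0 / 12.0
    swap_interval: float = 1000.0
    thermostat_rate: float = 0.1
    frame_interval: float = 50.0
    analysis_t_min: float = 0.4
    analysis_t_max: float = 0.8
    energy_bin_width: float = 1.0
    pmf_bin_width: tuple[float, float] = (1.0, 1.0)
    basin_depth_cutoff: float = 1.0
    cluster_max_frames: int = 400
    native_contact_cutoff: float = 7.5
    well_depth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "ladder_min", "ladder_max", "ladder_increment", "horizon",
            "swap_interval", "frame_interval", "analysis_t_min",
            "analysis_t_max", "energy_bin_width", "basin_depth_cutoff",
            "native_contact_cutoff", "well_depth",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thermostat_rate < 0:
            raise ValueError("thermostat_rate must be non-negative")
        if not (0 <= self.equilibration_fraction < 1):
            raise ValueError("equilibration_fraction must lie in [0, 1)")
        usable = (1 - self.equilibration_fraction) * self.horizon
        if usable < 2 * self.frame_interval:
            raise ValueError(
                "horizon leaves no frames after the equilibration discard"
            )

    # -- serialization: YAML round-trips bit-identically ---------------

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["pmf_bin_width"] = list(d["pmf_bin_width"])
        return yaml.safe_dump(d, sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["pmf_bin_width"] = tuple(d["pmf_bin_width"])
        return RunConfig(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def topology(self) -> ChainTopology:
        return mini_bundle_topology(self.helix_len, self.hinge_len, self.tail_len)

    def go_params(self) -> GoParameterSet:
        return GoParameterSet(
            native_contact_cutoff=self.native_contact_cutoff,
            native_well_depth=self.well_depth,
        )


@dataclass
class PipelineResult:
    config: RunConfig
    ensemble: ReplicaEnsemble
    cv_curve: wham.CvCurve
    state_temperatures: dict[str, float]
    surfaces: dict[str, landscape.FreeEnergySurface]
    basins: dict[str, np.ndarray]
    clusters: dict[str, analysis.ClusterResult]
    centroid_frames: dict[str, np.ndarray]
    mobility: tuple[np.ndarray, float, float]
    manifest: dict


def _nearest_slot(ladder_temps: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(ladder_temps - t)))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full protocol and (optionally) write a report directory.

    Stages: build the Gō bundle → replica-exchange DMD → equilibration
    discard → WHAM Cv with extrema → T1..T4 labels → PMF at each labelled
    temperature → lowest-basin extraction → leader clustering → centroid,
    distance-matrix and geometry reports.  Stage failures propagate with
    the stage name attached; previously written outputs are kept.
    """
    manifest: dict = {"config_hash": config.config_hash, "stages": {}}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())

    def _write(name: str, text: str) -> None:
        if out is not None:
            (out / name).write_text(text)
            manifest["stages"].setdefault("outputs", []).append(name)

    stage = "build"
    try:
        topology = config.topology()
        model, start = build_mini_bundle(topology, config.go_params(), seed=config.seed)
        ladder = build_ladder(
            config.ladder_min, config.ladder_max, config.ladder_increment
        )
        manifest["stages"]["build"] = {
            "n_beads": topology.n_beads,
            "n_native_contacts": len(model.pairs_of_class("native")),
            "n_replicas": len(ladder),
        }
        _write("potentials.json", model.to_json())

        stage = "rex"
        ensemble = run_rex(
            model,
            start,
            ladder,
            n_timesteps=config.horizon,
            swap_interval=config.swap_interval,
            thermostat_rate=config.thermostat_rate,
            frame_interval=config.frame_interval,
            seed=config.seed,
        )
        counts, mob_mean, mob_sd = replica_mobility(ensemble)
        manifest["stages"]["rex"] = {
            "swap_acceptance": ensemble.swap_acceptance_rate(),
            "replica_mobility_mean": mob_mean,
            "replica_mobility_sd": mob_sd,
        }
        _write("swap_history.tsv", ensemble.swap_history_tsv())

        stage = "wham"
        series_all = wham.discard_equilibration(
            ensemble.energy_series,
            ensemble.energy_times,
            ladder.temperatures,
            config.equilibration_fraction,
        )
        series = {
            t: v
            for t, v in series_all.items()
            if config.analysis_t_min - 1e-9 <= t <= config.analysis_t_max + 1e-9
        }
        hists = wham.EnergyHistogramSet.from_series(series, config.energy_bin_width)
        solution = wham.wham_solve(hists)
        t_grid = np.arange(
            config.analysis_t_min, config.analysis_t_max + wham.CV_GRID_STEP / 2,
            wham.CV_GRID_STEP,
        )
        cv_curve = wham.heat_capacity(solution, t_grid)
        _write("cv.tsv", cv_curve.to_tsv())
        manifest["stages"]["wham"] = {
            "iterations": solution.n_iterations,
            "peaks_kelvin": [t / KB for t in cv_curve.peaks],
            "minima_kelvin": [t / KB for t in cv_curve.minima],
        }

        stage = "state_temperatures"
        states = landscape.assign_state_temperatures(cv_curve)
        manifest["stages"]["state_temperatures"] = {
            k: {"reduced": v, "kelvin": v / KB} for k, v in states.items()
        }
        _write(
            "state_temperatures.json",
            json.dumps(manifest["stages"]["state_temperatures"], indent=1),
        )

        stage = "landscape"
        helix_sel = topology.helix_indices()
        ladder_temps = np.asarray(ladder.temperatures)
        eq_cut = config.equilibration_fraction * config.horizon
        surfaces: dict[str, landscape.FreeEnergySurface] = {}
        basins: dict[str, np.ndarray] = {}
        clusters: dict[str, analysis.ClusterResult] = {}
        centroid_frames: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(config.seed + 1)
        for label, t_state in states.items():
            slot = _nearest_slot(ladder_temps, t_state)
            times, pos = ensemble.frames_at_slot(slot)
            keep = times > eq_cut
            pos = pos[keep]
            if len(pos) < 10:
                continue
            series_rc = landscape.coordinate_series(
                pos, start.positions, helix_sel, temperature=ladder_temps[slot]
            )
            surf = landscape.compute_pmf(series_rc, config.pmf_bin_width)
            surfaces[label] = surf
            _write(f"pmf_{label}.tsv", surf.to_tsv())
            basin = landscape.extract_basin(series_rc, surf, config.basin_depth_cutoff)
            basins[label] = basin
            _write(f"basin_{label}.txt", "\n".join(str(k) for k in basin) + "\n")
            pick = basin
            if len(pick) > config.cluster_max_frames:
                pick = np.sort(
                    rng.choice(pick, size=config.cluster_max_frames, replace=False)
                )
            cl = analysis.leader_cluster(pos[pick], helix_sel)
            clusters[label] = cl
            centroid_frames[label] = pos[pick][cl.centroids[0]]
            _write(f"clusters_{label}.tsv", cl.to_tsv())
            if out is not None:
                write_beads_pdb(out / f"centroid_{label}.pdb", centroid_frames[label], topology)
            dm = analysis.distance_matrix(pos[pick])
            _write(f"distance_matrix_{label}.tsv", dm.to_tsv())
            geo = analysis.geometry_report(pos[pick], topology)
            geo_lines = ["end_to_end_A\ttheta_deg\tphi_deg"]
            geo_lines += [
                f"{e:.4f}\t{th:.3f}\t{ph:.3f}"
                for e, th, ph in zip(geo.end_to_end, geo.theta, geo.phi)
            ]
            _write(f"geometry_{label}.tsv", "\n".join(geo_lines) + "\n")
            helix_frac = analysis.helicity_profile(
                {ladder_temps[slot]: pos[pick][::4]}, topology
            )[ladder_temps[slot]]
            hel_lines = ["residue\tH\tB\tL"]
            hel_lines += [
                f"{r + 1}\t{helix_frac['H'][r]:.3f}\t{helix_frac['B'][r]:.3f}"
                f"\t{helix_frac['L'][r]:.3f}"
                for r in range(topology.n_beads)
            ]
            _write(f"helicity_{label}.tsv", "\n".join(hel_lines) + "\n")

        stage = "report"
        result = PipelineResult(
            config=config,
            ensemble=ensemble,
            cv_curve=cv_curve,
            state_temperatures=states,
            surfaces=surfaces,
            basins=basins,
            clusters=clusters,
            centroid_frames=centroid_frames,
            mobility=(counts, mob_mean, mob_sd),
            manifest=manifest,
        )
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return result
    except Exception as exc:
        if out is not None:
            manifest["failed_stage"] = stage
            manifest["error"] = repr(exc)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
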