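"""Workflow orchestration: wires the stages into the two analysis chains
(BEMD -> FEL -> basins; per-intermediate ensembles -> statistics -> pathway
summary), with YAML-configurable runs, deterministic outputs and a
checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bemd, config, ensemble, fel, io, synthetic
from .geometry import build_native_contacts, cv_trace

log = logging.getLogger("gqfold")

WORKFLOWS = (
    "bemd-toy", "fel", "cluster", "analyze-ensemble", "unfold-pathways",
    "full-synthetic", "make-fixtures",
)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""


@dataclass
class RunConfig:
    """One workflow invocation: explicit seed, inputs, thresholds, outputs."""

    workflow: str
    outdir: str
    seed: int = 0
    overwrite: bool = False
    native_pdb: str | None = None
    trajectory_pdb: str | None = None
    samples_csv: str | None = None
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ConfigError(f"unknown workflow {self.workflow!r}; pick one of {WORKFLOWS}")
        for attr in ("native_pdb", "trajectory_pdb", "samples_csv"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr} path does not exist: {p}")
        out = Path(self.outdir)
        if out.exists() and any(out.iterdir()) and not self.overwrite:
            raise ConfigError(
                f"output directory {out} is not empty; pass overwrite to reuse it")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Report:
    """Collects written files and summary numbers for the manifest."""

    def __init__(self, outdir: Path, cfg: RunConfig):
        self.outdir = outdir
        self.cfg = cfg
        self.files: list[Path] = []
        self.summary: dict = {}

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.files.append(p)
        return p

    def finish(self) -> dict:
        summary_path = self.outdir / "summary.json"
        summary_path.write_text(json.dumps(self.summary, indent=1, sort_keys=True))
        self.files.append(summary_path)
        manifest = {
            "workflow": self.cfg.workflow,
            "seed": self.cfg.seed,
            "params": self.cfg.params,
            "files": [
                {"name": p.name, "sha256": _sha256(p)}
                for p in self.files if p.exists()
            ],
        }
        (self.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        return self.summary


def run_workflow(cfg: RunConfig) -> dict:
    """Execute one workflow; returns the machine-readable summary dict.

    Identical configs and seeds produce byte-identical summary files.  A
    stage failure aborts with the stage name and cause.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = _Report(outdir, cfg)
    chains = {
        "bemd-toy": [_stage_bemd_toy],
        "fel": [_stage_fel_from_csv],
        "cluster": [_stage_cluster],
        "analyze-ensemble": [_stage_analyze_ensemble],
        "unfold-pathways": [_stage_unfold],
        "full-synthetic": [_stage_bemd_toy, _stage_analyze_ensemble, _stage_unfold],
        "make-fixtures": [_stage_fixtures],
    }
    for stage in chains[cfg.workflow]:
        t0 = time.perf_counter()
        try:
            stage(cfg, report)
        except Exception as exc:
            raise StageError(f"stage {stage.__name__.lstrip('_')} failed: {exc}") from exc
        log.info("%s done in %.2f s", stage.__name__.lstrip("_"), time.perf_counter() - t0)
    return report.finish()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_bemd_toy(cfg: RunConfig, report: _Report) -> None:
    """BEMD on a two-basin 2D landscape; FEL and basins from the neutral
    replicas; exchange diagnostics."""
    p = cfg.params
    landscape = synthetic.make_analytic_landscape(
        p.get("landscape", "two_basin_2d"), **p.get("landscape_params", {}))
    schedule = bemd.Schedule(
        dt=p.get("dt", 1e-3),
        deposit_stride=p.get("deposit_stride", config.HILL_STRIDE),
        exchange_stride=p.get("exchange_stride", 0.005),
        sample_stride=p.get("sample_stride", 1e-3),
        total_time=p.get("total_time", 4.0),
    )
    cvs = [
        bemd.CoordinateCV("x", 0, grid_range=landscape.domain),
        bemd.CoordinateCV("y", 1, grid_range=landscape.domain),
    ][: landscape.dimension]
    n_biased = p.get("n_biased", min(2, len(cvs)))
    result = bemd.run_bemd(
        landscape, cvs, n_biased=n_biased, n_neutral=p.get("n_neutral", 2),
        schedule=schedule, widths=p.get("widths", [0.1] * len(cvs)),
        height=p.get("height", config.HILL_HEIGHT),
        temperature=p.get("temperature", config.DEFAULT_TEMPERATURE),
        seed=cfg.seed, x0=p.get("x0", landscape.minima[0] if landscape.minima else None),
    )
    for i, rep in enumerate(result.replicas):
        np.savetxt(
            report.path(f"trace_replica{i}.csv"),
            np.column_stack([result.times, result.traces[i]]),
            delimiter=",", comments="",
            header="time_ns," + ",".join(result.cv_names), fmt="%.6g")
        if rep.cv is not None:
            io.write_kernels_csv(report.path(f"kernels_replica{i}.csv"), rep.bias)
    io.write_exchange_log_csv(report.path("exchange_log.csv"), result.exchange_logs)

    neutral = [i for i, r in enumerate(result.replicas) if r.cv is None]
    samples = np.vstack([result.traces[i] for i in neutral])
    surface = fel.estimate_fel(
        samples, bins=p.get("fel_bins", 30),
        temperature=p.get("temperature", config.DEFAULT_TEMPERATURE),
        axes=tuple(result.cv_names)[: samples.shape[1]],
        min_count=p.get("fel_min_count", 5),
    )
    io.write_fel_json(report.path("fel.json"), surface)
    io.write_fel_csv(report.path("fel.csv"), surface)
    basins = fel.identify_basins(surface)
    diags = fel.exchange_diagnostics(result.exchange_logs)
    report.summary["bemd"] = {
        "n_basins": basins.n_basins,
        "basin_minima": [
            {"bin": list(map(int, b)), "free_energy_kj_mol": round(v, 6)}
            for b, v in basins.minima
        ],
        "mean_acceptance": [
            None if r.mean_acceptance is None else round(r.mean_acceptance, 6)
            for r in diags.replicas
        ],
        "exchange_r_squared": [
            None if r.r_squared is None else round(r.r_squared, 6)
            for r in diags.replicas
        ],
    }


def _load_native(cfg: RunConfig):
    if cfg.native_pdb:
        return io.read_structure(cfg.native_pdb)
    return synthetic.make_toy_quadruplex(seed=cfg.seed)


def _load_trajectory(cfg: RunConfig, native):
    if cfg.trajectory_pdb:
        return io.read_trajectory(
            cfg.trajectory_pdb, frame_stride=cfg.params.get("frame_stride", 1.0))
    spec = synthetic.default_intermediate_spec(seed=cfg.seed)
    spec.n_frames = cfg.params.get("n_frames", spec.n_frames)
    return synthetic.make_intermediate_ensemble(spec, native)


def _stage_cluster(cfg: RunConfig, report: _Report) -> None:
    native = _load_native(cfg)
    traj = _load_trajectory(cfg, native)
    clusters = ensemble.leader_cluster(
        traj, threshold=cfg.params.get("cluster_threshold", config.CLUSTER_THRESHOLD))
    io.write_cluster_csv(report.path("clusters.csv"), clusters)
    report.summary["clusters"] = {
        "n_clusters": clusters.n_clusters,
        "populations": [round(float(x), 6) for x in clusters.populations],
    }


def _stage_analyze_ensemble(cfg: RunConfig, report: _Report) -> None:
    """Per-intermediate statistics on a (synthetic or read) ensemble."""
    native = _load_native(cfg)
    traj = _load_trajectory(cfg, native)
    contacts = build_native_contacts(native)
    times, cvs = cv_trace(traj, native, contacts)
    io.write_cv_trace_csv(report.path("cv_trace.csv"), times, cvs)

    clusters = ensemble.leader_cluster(
        traj, threshold=cfg.params.get("cluster_threshold", config.CLUSTER_THRESHOLD))
    io.write_cluster_csv(report.path("clusters.csv"), clusters)
    hmap = ensemble.hbond_map(traj, native=native)
    io.write_hbond_csv(report.path("hbond_map.csv"), hmap)
    profile = ensemble.ion_binding_profile(traj)
    io.write_ion_profile_csv(report.path("ion_profile.csv"), profile)
    traces = ensemble.glycosidic_summary(traj)
    indices = [nt.index for nt in traj.frames[0].nucleotides]
    io.write_glycosidic_csv(report.path("glycosidic.csv"), traces, indices)

    report.summary["ensemble"] = {
        "n_frames": len(traj),
        "n_clusters": clusters.n_clusters,
        "mean_bound_ions": round(profile.mean_bound_count, 6),
        "fluctuating_nucleotides": [
            idx for idx, tr in zip(indices, traces) if tr.classification == "fluctuating"
        ],
    }


def _stage_unfold(cfg: RunConfig, report: _Report) -> None:
    """Unfolding trajectories -> leader-cluster stage labels -> pathway graph."""
    native = _load_native(cfg)
    multiplicities = cfg.params.get("pathway_multiplicities", [8, 1, 1])
    pathways = cfg.params.get("pathways")
    if pathways is None:
        pathways = [
            (("native", "triplex", "hairpin", "unfolded"), multiplicities[0]),
            (("native", "misfolded", "unfolded"), multiplicities[1]),
            (("native", "unfolded"), multiplicities[2]),
        ]
    trajs, _true_labels = synthetic.make_unfolding_set(
        native, pathways, seed=cfg.seed)
    # pool all frames, cluster once, then map each trajectory to cluster ids
    all_frames = [fr for tr in trajs for fr in tr.frames]
    clusters = ensemble.leader_cluster(
        all_frames,
        threshold=cfg.params.get("unfold_threshold", config.UNFOLD_CLUSTER_THRESHOLD))
    label_sequences = []
    k = 0
    for tr in trajs:
        label_sequences.append(
            [int(c) for c in clusters.membership[k:k + len(tr.frames)]])
        k += len(tr.frames)
    graph = ensemble.build_pathway_graph(label_sequences)
    report.path("pathways.json").write_text(
        json.dumps(graph.to_json_dict(), indent=1, sort_keys=True))
    report.path("pathways.dot").write_text(graph.to_dot())
    report.summary["pathways"] = {
        "n_trajectories": graph.n_trajectories,
        "edge_counts": sorted(graph.edges.values(), reverse=True),
        "path_counts": sorted(graph.paths.values(), reverse=True),
    }


def _stage_fel_from_csv(cfg: RunConfig, report: _Report) -> None:
    """FEL + basins from a CSV of CV samples (columns = 1 or 2 CVs)."""
    if not cfg.samples_csv:
        raise ConfigError("the fel workflow needs samples_csv")
    samples = np.loadtxt(cfg.samples_csv, delimiter=",", skiprows=1, ndmin=2)
    surface = fel.estimate_fel(
        samples[:, : cfg.params.get("n_axes", min(2, samples.shape[1]))],
        bins=cfg.params.get("fel_bins", config.FEL_BINS),
        temperature=cfg.params.get("temperature", config.DEFAULT_TEMPERATURE),
    )
    io.write_fel_json(report.path("fel.json"), surface)
    io.write_fel_csv(report.path("fel.csv"), surface)
    basins = fel.identify_basins(surface)
    report.summary["fel"] = {"n_basins": basins.n_basins}


def _stage_fixtures(cfg: RunConfig, report: _Report) -> None:
    """Write the packaged synthetic fixtures: native PDB, a short ensemble
    PDB, and the default ensemble spec as YAML."""
    native = synthetic.make_toy_quadruplex(seed=cfg.seed)
    io.write_structure(report.path("native.pdb"), native)
    spec = synthetic.default_intermediate_spec(seed=cfg.seed)
    spec.n_frames = cfg.params.get("n_frames", 50)
    traj = synthetic.make_intermediate_ensemble(spec, native)
    io.write_trajectory(report.path("ensemble.pdb"), traj)
    report.path("ensemble_spec.yaml").write_text(yaml.safe_dump({
        "n_frames": spec.n_frames,
        "frame_stride": spec.frame_stride,
        "hbond_probs": {f"{i}-{j}": p for (i, j), p in spec.hbond_probs.items()},
        "ion_site_occupancies": list(spec.ion_site_occupancies),
        "chi_dwell": {k: list(v) for k, v in spec.chi_dwell.items()},
        "noise": spec.noise,
        "seed": spec.seed,
    }))
    report.summary["fixtures"] = {"n_frames": spec.n_frames}
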