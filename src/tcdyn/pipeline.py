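"""End-to-end pipeline orchestration.

Runs (optionally) simulate → filter → cluster → pathways → network with a
single :class:`RunConfig`, writing per-stage TSV/JSON outputs plus a run
manifest (config hash, seed, package version, stage timings).  All
randomness derives from the one config seed via fixed per-stage substreams,
so a rerun with the same config reproduces every output byte-for-byte and
stages can be rerun independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import (
    UNASSIGNED,
    select_cluster_number,
    standardize_profiles,
    summarize_patterns,
)
from .dynamics import classify_dynamic, count_updown_by_timepoint
from .matrix import TimeCourseMatrix, load_expression
from .network import build_network, hub_overlap_stats
from .pathways import (
    cluster_timepoint_enrichment,
    enrichment_timecourse,
    find_coregulation_clusters,
    read_gmt,
    signature_correlation,
    write_gmt,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]

STAGES = ("simulate", "filter", "cluster", "pathways", "network")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline in one place."""

    out_dir: str = "tcdyn_run"
    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    reference_list_paths: list = field(default_factory=list)
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    # filter
    alpha: float = 0.01
    fc_cut: float = 2.0
    # cluster
    fuzzifier: float = 1.25
    membership: float = 0.5
    overlap_r: float = 0.9
    c_min: int = 2
    c_max: int = 10
    # pathways
    p_cut: float = 0.05
    correlation_on: str = "samples"
    # network
    hub_fraction: float = 0.10
    r2_target: float = 0.8
    # simulate
    n_static: int = 4400
    n_dynamic: int = 600
    noise_sd: float = 0.25
    base_mean: float = 6.0
    amplitude: float = 2.0
    n_sets: int = 15
    set_size: int = 25
    aligned_fraction: float = 1.0
    hub_n: int = 5
    hub_strength: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.p_cut < 1:
            raise ValueError("alpha and p_cut must lie in (0, 1)")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if not 0 < self.membership <= 1 or not 0 < self.hub_fraction <= 1:
            raise ValueError("membership and hub_fraction must lie in (0, 1]")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(config: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    A stage failure halts the run with a stage-named :class:`StageError`;
    partial outputs are retained alongside a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            try:
                _RUNNERS[stage](config, out, state)
            except Exception as exc:  # noqa: BLE001 - converted to stage-named error
                (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
                raise StageError(stage, exc) from exc
            manifest["stages"][stage] = {
                "status": "completed",
                "seconds": round(time.perf_counter() - t0, 3),
            }
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    failed = out / "FAILED"
    if failed.exists() and all(
        s.get("status") == "completed" for s in manifest["stages"].values()
    ):
        failed.unlink()
    return manifest


# ----------------------------------------------------------------------
def _run_simulate(config: RunConfig, out: Path, state: dict) -> None:
    from .simulate import HubSpec, SimulationConfig, generate_gene_sets, generate_timecourse

    sim = SimulationConfig(
        n_static=config.n_static,
        n_dynamic=config.n_dynamic,
        noise_sd=config.noise_sd,
        base_mean=config.base_mean,
        amplitude=config.amplitude,
        n_sets=config.n_sets,
        set_size=config.set_size,
        aligned_fraction=config.aligned_fraction,
        hub_spec=HubSpec(n_hubs=config.hub_n, strength=config.hub_strength)
        if config.hub_n > 0
        else None,
        seed=_stage_seed(config, "simulate"),
    )
    matrix, truth = generate_timecourse(sim)
    sets = generate_gene_sets(truth, sim)
    matrix.to_tsv(out / "expression.tsv", out / "design.tsv")
    write_gmt(sets, out / "gene_sets.gmt")
    truth.to_json(out / "ground_truth.json")
    state.update(matrix=matrix, truth=truth, sets=sets)


def _require_matrix(config: RunConfig, state: dict) -> TimeCourseMatrix:
    if "matrix" not in state:
        if not config.matrix_path or not config.design_path:
            raise FileNotFoundError(
                "no simulated matrix in this run and matrix_path/design_path not set"
            )
        for p in (config.matrix_path, config.design_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        state["matrix"] = load_expression(config.matrix_path, config.design_path)
    return state["matrix"]


def _run_filter(config: RunConfig, out: Path, state: dict) -> None:
    matrix = _require_matrix(config, state)
    result = classify_dynamic(matrix, alpha=config.alpha, fc_cut=config.fc_cut)
    result.table.rename_axis("gene_id").to_csv(out / "dynamic_test.tsv", sep="\t")
    counts = count_updown_by_timepoint(result, matrix)
    counts.to_csv(out / "updown_counts.tsv", sep="\t")
    (out / "dynamic_fraction.json").write_text(
        json.dumps(
            {
                "n_genes": int(len(result.table)),
                "n_dynamic": int(result.table["is_dynamic"].sum()),
                "dynamic_fraction": result.dynamic_fraction,
            },
            indent=1,
        )
    )
    state["dynamics"] = result


def _run_cluster(config: RunConfig, out: Path, state: dict) -> None:
    import pandas as pd

    matrix = _require_matrix(config, state)
    if "dynamics" not in state:
        state["dynamics"] = classify_dynamic(matrix, alpha=config.alpha, fc_cut=config.fc_cut)
    dyn_ids = state["dynamics"].dynamic_ids
    profiles = standardize_profiles(matrix, dyn_ids)
    sel = select_cluster_number(
        profiles,
        c_range=range(config.c_min, config.c_max + 1),
        m=config.fuzzifier,
        overlap_r=config.overlap_r,
        seed=_stage_seed(config, "cluster"),
        membership_threshold=config.membership,
    )
    model = sel.model
    tax = summarize_patterns(model, time_points=matrix.time_order)
    pd.DataFrame(
        model.centroids, columns=[str(t) for t in matrix.time_order]
    ).rename_axis("cluster").to_csv(out / "centroids.tsv", sep="\t")
    model.U.rename_axis("gene_id").to_csv(out / "memberships.tsv", sep="\t")
    model.assignments.rename_axis("gene_id").to_csv(out / "assignments.tsv", sep="\t")
    tax.astype(str).to_csv(out / "pattern_taxonomy.tsv", sep="\t")
    state["patterns"] = model
    state["cluster_selection"] = sel


def _run_pathways(config: RunConfig, out: Path, state: dict) -> None:
    matrix = _require_matrix(config, state)
    if "sets" not in state:
        if not config.gmt_path:
            raise FileNotFoundError("pathways stage needs gmt_path or a simulate stage")
        if not Path(config.gmt_path).exists():
            raise FileNotFoundError(f"GMT file not found: {config.gmt_path}")
        state["sets"] = read_gmt(config.gmt_path)
    track = enrichment_timecourse(matrix, state["sets"])
    corr = signature_correlation(track, matrix=matrix, on=config.correlation_on)
    clusters = find_coregulation_clusters(corr, p_cut=config.p_cut)
    track.ES.rename_axis("signature").to_csv(out / "ssgsea_scores.tsv", sep="\t")
    corr.r.rename_axis("signature").to_csv(out / "signature_correlation.tsv", sep="\t")
    (out / "coregulation_clusters.json").write_text(
        json.dumps({f"cluster_{i}": c.members for i, c in enumerate(clusters)}, indent=1)
    )
    if clusters:
        tables = cluster_timepoint_enrichment(track, clusters, matrix)
        for ci, tbl in tables.items():
            tbl.to_csv(out / f"cluster_{ci}_timecourse.tsv", sep="\t")
    state.update(track=track, corr=corr, coreg_clusters=clusters)


def _run_network(config: RunConfig, out: Path, state: dict) -> None:
    matrix = _require_matrix(config, state)
    if "patterns" not in state:
        raise RuntimeError("network stage needs the cluster stage in the same run")
    model = state["patterns"]
    hubs_all: dict = {}
    networks: dict = {}
    for k in range(model.c):
        members = list(model.assignments.index[model.assignments == k])
        if len(members) < 3:
            continue
        X = matrix.values.loc[members]
        net = build_network(
            X,
            beta=None if len(members) >= 20 else 6,
            r2_target=config.r2_target,
            hub_fraction=config.hub_fraction,
        )
        networks[k] = net
        hubs_all[f"pattern_{k}"] = net.hubs
        net.kWithin.to_frame().assign(kME=net.kME).rename_axis("gene_id").to_csv(
            out / f"pattern_{k}_connectivity.tsv", sep="\t"
        )
    (out / "hubs.json").write_text(json.dumps(hubs_all, indent=1))
    state["networks"] = networks
    if config.reference_list_paths:
        universe = list(matrix.gene_ids)
        refs = [
            [g for g in Path(p).read_text().split() if g] for p in config.reference_list_paths
        ]
        all_hubs = sorted({g for hs in hubs_all.values() for g in hs})
        stats_ = hub_overlap_stats(
            all_hubs, refs, universe, seed=_stage_seed(config, "network")
        )
        (out / "hub_overlap.json").write_text(
            json.dumps(
                {
                    "observed_percent": stats_.observed_percent,
                    "random_mean_percent": stats_.random_mean,
                    "random_percents": list(stats_.random_percents),
                },
                indent=1,
            )
        )
        state["hub_overlap"] = stats_


_RUNNERS = {
    "simulate": _run_simulate,
    "filter": _run_filter,
    "cluster": _run_cluster,
    "pathways": _run_pathways,
    "network": _run_network,
}
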