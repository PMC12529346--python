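"""End-to-end orchestration: simulate -> QC -> z-score -> pool -> select k ->
cluster -> metrics -> statistics -> report.

Every stage reads its inputs from, and writes its outputs to, the configured
output directory, so each can be re-run independently (and the CLI exposes
them as subcommands). All randomness flows from the single config seed;
re-running a stage with the same config reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas, io, metrics as metrics_mod, stats as stats_mod
from .clustering import (
    CoactivationPatterns,
    assign_states,
    centroid_similarity_matrix,
    concat_frames,
    frame_centroid_similarity,
    label_caps_by_network,
)
from .synthetic import CohortSpec, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "report"]

#: Reporting order of networks, mirroring the canonical state numbering
#: (visual, somatomotor, default-mode, ventral DMN stand-in, salience,
#: executive).
NETWORK_REPORT_ORDER = ["Vis", "SomMot", "Default", "Limbic", "SalVentAttn", "Cont"]


@dataclass
class PipelineConfig:
    """All pipeline settings. ``simulate`` switches between generating a
    synthetic cohort and reading an existing manifest."""

    out_dir: str = "capdyn_out"
    manifest: str | None = None
    parcel_table: str | None = None
    simulate: bool = True
    # synthetic cohort scale
    n_trd: int = 58
    n_hc: int = 56
    n_hc_longitudinal: int = 18
    n_rois: int = 454
    n_runs: int = 2
    frames_per_run: int = 250
    noise_sigma: float = 1.0
    # clustering
    k: int | None = None
    k_min: int = 2
    k_max: int = 15
    n_replicates: int = 100
    scan_replicates: int = 10
    max_iter: int = 1000
    silhouette: bool = False
    # metrics / QC / stats
    fd_threshold_mm: float = 0.5
    literal_tp: bool = False
    zscore_per_run: bool = True
    alpha: float = 0.05
    tr_seconds: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.fd_threshold_mm <= 0:
            raise ValueError("fd_threshold_mm must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _out(config) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: PipelineConfig) -> None:
    spec = CohortSpec(
        n_trd=config.n_trd,
        n_hc=config.n_hc,
        n_hc_longitudinal=config.n_hc_longitudinal,
        n_rois=config.n_rois,
        n_runs=config.n_runs,
        frames_per_run=config.frames_per_run,
        tr_seconds=config.tr_seconds,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
    )
    manifest, sessions, truth = simulate_cohort(spec)
    write_cohort(_out(config), manifest, sessions, truth)


def _load_inputs(config: PipelineConfig):
    out = _out(config)
    manifest_path = config.manifest or out / "manifest.tsv"
    parcel_path = config.parcel_table or out / "parcels.tsv"
    if not Path(manifest_path).exists():
        raise FileNotFoundError(
            f"manifest {manifest_path} not found (enable simulate or provide one)"
        )
    manifest = io.read_manifest(manifest_path)
    table = atlas.read_parcel_table(parcel_path)
    root = str(Path(manifest_path).parent)
    return manifest, table, root


def stage_qc(config: PipelineConfig) -> pd.DataFrame:
    manifest, _, _ = _load_inputs(config)
    retained, excluded = io.qc_mean_fd(manifest, config.fd_threshold_mm)
    out = _out(config)
    io.write_manifest(out / "manifest_qc.tsv", retained)
    excluded.to_csv(out / "excluded_sessions.tsv", sep="\t", index=False)
    logger.info("QC: %d rows retained, %d excluded", len(retained), len(excluded))
    return retained


def _load_zscored_sessions(config: PipelineConfig):
    manifest, table, root = _load_inputs(config)
    qc_path = _out(config) / "manifest_qc.tsv"
    if qc_path.exists():
        manifest = io.read_manifest(qc_path)
    sessions = io.load_cohort(manifest, table, root=root)
    # FD traces are not persisted per frame in the manifest; reattach from
    # the per-run mean as a flat trace for per-state motion summaries.
    by_key = {
        (str(r.subject_id), str(r.timepoint), int(r.run_index)): float(r.mean_fd)
        for r in manifest.itertuples()
    }
    for ts in sessions:
        fd = np.zeros(ts.n_frames)
        for run_idx, sl in enumerate(ts.run_slices()):
            fd[sl] = by_key[(ts.subject_id, ts.timepoint, run_idx)]
        ts.fd_mm = fd
    zs = [io.zscore_session(ts, per_run=config.zscore_per_run) for ts in sessions]
    return manifest, table, zs


def stage_cluster(config: PipelineConfig):
    manifest, table, sessions = _load_zscored_sessions(config)
    pool = concat_frames(sessions)
    model = CoactivationPatterns(
        pool,
        k=config.k,
        k_range=(config.k_min, config.k_max),
        n_replicates=config.n_replicates,
        max_iter=config.max_iter,
        scan_replicates=config.scan_replicates,
    )
    res = model.fit(seed=config.seed)
    res = res.reorder_by_network(table, NETWORK_REPORT_ORDER)
    out = _out(config)
    if res.selection_curve is not None:
        res.selection_curve.to_frame().to_csv(
            out / "k_curve.tsv", sep="\t", index=False, float_format="%.10g"
        )
        (out / "k_selection.json").write_text(
            json.dumps(res.selection_curve.elbow_fit or {}, indent=2)
        )
    res.save(out, parcel_ids=table["parcel_id"].tolist())
    lab = label_caps_by_network(res, table)
    lab.to_csv(out / "network_labels.tsv", sep="\t", float_format="%.6g")
    np.savetxt(
        out / "centroid_similarity.tsv", centroid_similarity_matrix(res), delimiter="\t", fmt="%.10g"
    )
    frame_centroid_similarity(pool, res).to_csv(
        out / "frame_similarity.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return res


def stage_metrics(config: PipelineConfig):
    manifest, table, sessions = _load_zscored_sessions(config)
    out = _out(config)
    meta = json.loads((out / "model.json").read_text())
    K = meta["k"]
    centroids = pd.read_csv(out / "centroids.tsv", sep="\t").to_numpy()
    labels_df = pd.read_csv(out / "labels.tsv", sep="\t")
    from .clustering import CapResults, FramePool

    pool = FramePool(
        frames=np.zeros((len(labels_df), centroids.shape[1])),
        index_map=labels_df[["subject_id", "group", "timepoint", "run_index", "frame_index"]],
    )
    res = CapResults(
        k=K,
        centroids=centroids,
        labels=labels_df["state"].to_numpy(),
        objective=meta["objective"],
        replicate_scores=meta["replicate_scores"],
        seed=meta["seed"],
        pool=pool,
    )
    items = []
    for ts in sessions:
        seq = assign_states(ts, res)
        items.append((seq, metrics_mod.session_metrics(seq, K, ts=ts, literal_tp=config.literal_tp)))
    table_long = metrics_mod.metrics_table(items, K)
    table_long.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    return table_long


def stage_stats(config: PipelineConfig):
    out = _out(config)
    manifest, _, _ = _load_inputs(config)
    qc_path = out / "manifest_qc.tsv"
    if qc_path.exists():
        manifest = io.read_manifest(qc_path)
    table_long = pd.read_csv(out / "metrics.tsv", sep="\t")
    K = int(table_long.loc[table_long["metric"] == "FT", "state_from"].max())
    analysis = stats_mod.CapDynamicsAnalysis(table_long, manifest, K=K, alpha=config.alpha)
    results = analysis.fit()
    # frame-similarity representativeness ANOVA (per state, across groups)
    sim_path = out / "frame_similarity.tsv"
    if sim_path.exists():
        sim = pd.read_csv(sim_path, sep="\t")
        for s in range(1, K + 1):
            sub = sim[sim["state"] == s]
            groups = [
                sub[(sub["group"] == "HC") & (sub["timepoint"] == "baseline")]["r"],
                sub[(sub["group"] == "TRD") & (sub["timepoint"] == "baseline")]["r"],
                sub[(sub["group"] == "TRD") & (sub["timepoint"] == "post")]["r"],
            ]
            try:
                res = stats_mod.oneway_anova(groups, name=f"frame_similarity_anova:state{s}")
            except ValueError:
                continue
            res.alpha_adjusted = config.alpha
            res.significant = bool(res.p < config.alpha)
            results.frame_similarity_anova.append(res)
            results.tests.append(res)
    results.to_frame().to_csv(out / "tests.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "families.json").write_text(json.dumps(results.family_summary(), indent=2))
    return results


def report(config: PipelineConfig) -> str:
    """Human-readable run summary regenerated from the saved outputs."""
    out = _out(config)
    needed = ["model.json", "metrics.tsv", "tests.tsv", "families.json"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline outputs: {missing}")
    meta = json.loads((out / "model.json").read_text())
    tests = pd.read_csv(out / "tests.tsv", sep="\t")
    families = json.loads((out / "families.json").read_text())
    table_long = pd.read_csv(out / "metrics.tsv", sep="\t")
    K = meta["k"]
    lines = [
        "CAP dynamics pipeline report",
        "============================",
        f"states (k): {K}   seed: {meta['seed']}   objective: {meta['objective']:.4f}",
    ]
    if meta.get("state_names"):
        lines.append("state networks: " + ", ".join(map(str, meta["state_names"])))
    lines.append("")
    ft = table_long[table_long["metric"] == "FT"]
    gm = (
        ft.groupby(["group", "timepoint", "state_from"])["value"].mean().unstack("state_from")
    )
    lines.append("mean fraction of time per state:")
    lines.append(gm.round(4).to_string())
    lines.append("")
    lines.append("Bonferroni families:")
    for name, f in families.items():
        lines.append(f"  {name}: m={f['m']}, threshold={f['threshold']:.4g}")
    lines.append("")
    sig = tests[tests["significant"] == True]  # noqa: E712
    lines.append(f"tests: {len(tests)} total, {len(sig)} significant at family thresholds")
    cols = ["name", "statistic", "df", "p", "family", "alpha_adjusted", "significant"]
    with pd.option_context("display.width", 160, "display.max_rows", 1000):
        lines.append(tests[cols].round({"statistic": 3, "df": 1}).to_string(index=False))
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text


STAGES = ["simulate", "qc", "cluster", "metrics", "stats", "report"]


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; any failure aborts with the stage named.
    Returns the output directory."""
    out = _out(config)
    config.to_yaml(out / "config.yaml")
    log = {"seed": config.seed, "stages": []}
    for stage in STAGES:
        if stage == "simulate" and not config.simulate:
            continue
        fn = {
            "simulate": stage_simulate,
            "qc": stage_qc,
            "cluster": stage_cluster,
            "metrics": stage_metrics,
            "stats": stage_stats,
            "report": report,
        }[stage]
        logger.info("running stage %s", stage)
        try:
            fn(config)
        except Exception as e:
            log["stages"].append({"stage": stage, "status": "failed", "error": str(e)})
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
            raise StageError(stage, e) from e
        log["stages"].append({"stage": stage, "status": "ok"})
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
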