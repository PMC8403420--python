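"""End-to-end orchestration: simulate → deconvolve → mvp → cluster →
therapy-shift → enrich → dmg → validate, with a run manifest.

Every stage writes plain-text artifacts (TSV/JSON) into the output
directory; the manifest records the config snapshot, package version,
SHA-256 checksum of every produced file, timestamps and accumulated
warnings. All randomness flows from the single config seed, so repeated
runs at a fixed seed produce byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_io import (
    read_atlas,
    read_beta_matrix,
    read_gene_sets,
    read_probe_annotation,
    read_sample_sheet,
    read_therapy_timeline,
    write_atlas,
    write_beta_matrix,
    write_gene_sets,
    write_probe_annotation,
    write_sample_sheet,
    write_therapy_timeline,
)
from .deconvolution import deconvolve_cohort, fractions_frame, labels_from_results
from .dmg_analysis import call_dmgs, validate_dmgs
from .synthetic_cohort import (
    Cohort,
    SimulationConfig,
    generate_cohort,
    generate_gene_sets,
)
from .temporal_dynamics import (
    cluster_trajectories,
    compute_probe_sd,
    gene_envelopes,
    pca_qc,
    select_mvps,
    stability_summary,
)
from .therapy_response import detect_shifts, enrich_gene_sets, summarize_shifts

logger = logging.getLogger(__name__)

STAGES = ("simulate", "deconvolve", "mvp", "cluster", "therapy_shift",
          "enrich", "dmg", "validate")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Thresholds, input paths and the master seed for one pipeline run."""

    outdir: str = "methylodyn_run"
    seed: int = 0
    simulate: bool = True
    # input paths (required when simulate is False)
    beta_path: str | None = None
    sheet_path: str | None = None
    timeline_path: str | None = None
    atlas_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    # thresholds
    mvp_fraction: float = 0.05
    shift_threshold: float = 0.1
    dmg_delta_threshold: float = 0.1
    q_threshold: float = 0.05
    detect_threshold: float = 0.03
    substantial_threshold: float = 0.10
    k_max: int = 8
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        for name, lo, hi in (("mvp_fraction", 0.0, 1.0),
                             ("shift_threshold", 0.0, 1.0),
                             ("dmg_delta_threshold", 0.0, 1.0),
                             ("q_threshold", 0.0, 1.0),
                             ("detect_threshold", 0.0, 1.0),
                             ("substantial_threshold", 0.0, 1.0)):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise PipelineConfigError(f"{name}={v} outside ({lo}, {hi})")
        if self.detect_threshold > self.substantial_threshold:
            raise PipelineConfigError("detect_threshold above substantial_threshold")
        if not self.simulate:
            required = ("beta_path", "sheet_path", "timeline_path",
                        "atlas_path", "annotation_path")
            missing = [n for n in required if getattr(self, n) is None]
            if missing:
                raise PipelineConfigError(
                    f"simulate is off but input paths missing: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        raw.update(overrides)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["cell_types"] = list(sim["cell_types"])
            if sim.get("therapy_windows"):
                sim["therapy_windows"] = [dataclasses.asdict(w) if dataclasses.is_dataclass(w) else w
                                          for w in self.simulation.therapy_windows]
            d["simulation"] = sim
        return d


@dataclass
class RunManifest:
    """Record of one pipeline run: config, checksums, warnings, timing."""

    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, outputs: dict[str, str]) -> None:
        self.stages[name] = {"outputs": outputs}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _checksum_all(outdir: Path, paths: list[Path]) -> dict[str, str]:
    return {str(p.relative_to(outdir)): _sha256(p) for p in sorted(paths)}


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


# ---------------------------------------------------------------------------
# Stage implementations (reusable by the CLI subcommands)
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> tuple[Cohort, list[Path]]:
    sim = config.simulation or SimulationConfig(seed=config.seed)
    cohort = generate_cohort(sim)
    gene_sets = generate_gene_sets(cohort.annotation, cohort.truth, seed=sim.seed)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": inputs / "beta.tsv",
        "sheet": inputs / "sample_sheet.csv",
        "timeline": inputs / "therapy_timeline.csv",
        "atlas": inputs / "atlas.csv",
        "annotation": inputs / "probe_annotation.csv",
        "gene_sets": inputs / "gene_sets.gmt",
        "truth": inputs / "ground_truth.json",
    }
    write_beta_matrix(cohort.beta, paths["beta"])
    write_sample_sheet(cohort.sheet, paths["sheet"])
    write_therapy_timeline(cohort.timeline, paths["timeline"])
    write_atlas(cohort.atlas, paths["atlas"])
    write_probe_annotation(cohort.annotation, paths["annotation"])
    write_gene_sets(gene_sets, paths["gene_sets"])
    _write_json(cohort.truth.summary_dict(), paths["truth"])
    return cohort, list(paths.values())


def stage_deconvolve(beta, atlas, sheet, config: PipelineConfig,
                     outdir: Path) -> tuple[list, dict, list[Path]]:
    results, summary = deconvolve_cohort(
        beta, atlas, sheet,
        detect_threshold=config.detect_threshold,
        substantial_threshold=config.substantial_threshold)
    frac_path = outdir / "deconvolution_fractions.tsv"
    fractions_frame(results).to_csv(frac_path, sep="\t", float_format="%.6g")
    summary_path = outdir / "deconvolution_summary.json"
    _write_json(summary, summary_path)
    return results, summary, [frac_path, summary_path]


def stage_mvp(beta, sheet, annotation, config: PipelineConfig,
              outdir: Path) -> tuple[dict, list[Path]]:
    """Per-subject probe SDs, MVP selection, stability and PCA QC."""
    mvp_sets = {}
    rows = []
    stability = {}
    for subject in sheet.subjects():
        samples = [r.sample_id for r in sheet.records_for(subject)]
        if len(samples) < 3:
            logger.warning("subject %s skipped in MVP stage (< 3 timepoints)",
                           subject)
            continue
        sds = compute_probe_sd(beta.subset(samples=samples))
        mvp = select_mvps(sds, config.mvp_fraction, annotation,
                          subject_id=subject)
        mvp_sets[subject] = mvp
        stability[subject] = stability_summary(sds)
        reg = set(mvp.regulatory)
        rows.extend({"subject_id": subject, "probe_id": p,
                     "sd": float(sds[p]), "regulatory": p in reg}
                    for p in mvp.selected)
    mvp_path = outdir / "mvps.tsv"
    pd.DataFrame(rows, columns=["subject_id", "probe_id", "sd", "regulatory"]) \
        .to_csv(mvp_path, sep="\t", index=False, float_format="%.6g")
    stab_path = outdir / "stability.json"
    _write_json({"per_subject": stability,
                 "pooled_mean": (sum(stability.values()) / len(stability))
                 if stability else None}, stab_path)
    pca = pca_qc(beta)
    pca_path = outdir / "pca.tsv"
    coords = pca.coordinates.copy()
    coords.to_csv(pca_path, sep="\t", float_format="%.6g",
                  index_label="sample_id")
    return mvp_sets, [mvp_path, stab_path, pca_path]


def stage_cluster(beta, sheet, annotation, mvp_sets, config: PipelineConfig,
                  outdir: Path) -> tuple[dict, list[Path]]:
    clusterings = {}
    cluster_json = {}
    env_rows = []
    for subject, mvp in sorted(mvp_sets.items()):
        probes = list(mvp.regulatory)
        if len(probes) < 2:
            logger.warning("subject %s skipped in clustering (< 2 regulatory MVPs)",
                           subject)
            continue
        samples = [r.sample_id for r in sheet.records_for(subject)]
        sub = beta.subset(probes=probes, samples=samples)
        clustering = cluster_trajectories(sub, k_max=config.k_max,
                                          subject_id=subject)
        clusterings[subject] = clustering
        cluster_json[subject] = {
            "n_clusters": clustering.n_clusters,
            "silhouette": clustering.silhouette,
            "labels": {p: int(c) for p, c in clustering.labels.items()},
        }
        for env in gene_envelopes(clustering, sub, annotation):
            for t, mean, lo, hi in zip(env.timepoints, env.mean,
                                       env.minimum, env.maximum):
                env_rows.append({
                    "subject_id": subject, "cluster": env.cluster,
                    "gene": env.gene, "sample_id": t, "mean": mean,
                    "min": lo, "max": hi, "n_probes": env.n_probes,
                })
    cl_path = outdir / "clustering.json"
    _write_json(cluster_json, cl_path)
    env_path = outdir / "gene_envelopes.tsv"
    pd.DataFrame(env_rows, columns=["subject_id", "cluster", "gene",
                                    "sample_id", "mean", "min", "max",
                                    "n_probes"]) \
        .to_csv(env_path, sep="\t", index=False, float_format="%.6g")
    return clusterings, [cl_path, env_path]


def stage_therapy_shift(beta, sheet, timeline, mvp_sets,
                        config: PipelineConfig, outdir: Path
                        ) -> tuple[list, list[Path]]:
    all_records = []
    for subject, mvp in sorted(mvp_sets.items()):
        for window in timeline.for_subject(subject):
            all_records.extend(detect_shifts(
                beta, mvp.regulatory, window, sheet,
                shift_threshold=config.shift_threshold))
    rec_rows = [{
        "subject_id": r.subject_id, "probe_id": r.probe_id,
        "therapy_class": r.therapy_class, "baseline_sample": r.baseline_sample,
        "delta_beta": r.delta_beta, "shifted": r.shifted,
        "direction": r.direction, "transient": r.transient,
    } for r in all_records]
    rec_path = outdir / "shift_records.tsv"
    pd.DataFrame(rec_rows, columns=["subject_id", "probe_id", "therapy_class",
                                    "baseline_sample", "delta_beta", "shifted",
                                    "direction", "transient"]) \
        .to_csv(rec_path, sep="\t", index=False, float_format="%.6g")
    report = summarize_shifts(all_records, timeline)
    rep_path = outdir / "shift_report.json"
    _write_json(report.to_records(), rep_path)
    return all_records, [rec_path, rep_path]


def stage_enrich(shift_records, mvp_sets, annotation, gene_sets,
                 config: PipelineConfig, outdir: Path) -> list[Path]:
    rows = []
    for subject, mvp in sorted(mvp_sets.items()):
        universe = annotation.genes_for_probes(mvp.regulatory)
        shifted_probes = {r.probe_id for r in shift_records
                          if r.subject_id == subject and r.shifted}
        foreground = annotation.genes_for_probes(shifted_probes) & universe
        if not universe:
            continue
        for res in enrich_gene_sets(foreground, universe, gene_sets,
                                    q_threshold=config.q_threshold):
            rows.append({
                "subject_id": subject, "set_name": res.set_name,
                "overlap": res.overlap, "set_size": res.set_size,
                "foreground_size": res.foreground_size,
                "universe_size": res.universe_size,
                "p": res.p, "q": res.q, "significant": res.significant,
            })
    path = outdir / "enrichment.tsv"
    pd.DataFrame(rows, columns=["subject_id", "set_name", "overlap",
                                "set_size", "foreground_size", "universe_size",
                                "p", "q", "significant"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.6g")
    return [path]


def stage_dmg(beta, annotation, sheet, labels, config: PipelineConfig,
              outdir: Path):
    table = call_dmgs(beta, annotation, sheet, labels,
                      delta_threshold=config.dmg_delta_threshold,
                      q_threshold=config.q_threshold,
                      mvp_fraction=config.mvp_fraction)
    rec_path = outdir / "dmg_records.tsv"
    table.records.to_csv(rec_path, sep="\t", index=False, float_format="%.6g")
    sum_path = outdir / "dmg_summary.json"
    _write_json({"summary": table.summary,
                 "per_subject": table.per_subject}, sum_path)
    return table, [rec_path, sum_path]


def stage_validate(dmg_table, config: PipelineConfig,
                   outdir: Path) -> tuple[object, list[Path]]:
    """Validate discovery DMGs in a paired synthetic cohort.

    The validation cohort shares the discovery cohort's design and planted
    effects but draws an independent noise realisation; its PC/NPC labels
    come from deconvolving the validation β matrix against the atlas.
    """
    sim = config.simulation or SimulationConfig(seed=config.seed)
    val_sim = dataclasses.replace(sim, noise_seed=sim.seed + 1_000_003)
    val = generate_cohort(val_sim)
    results, _ = deconvolve_cohort(
        val.beta, val.atlas, val.sheet,
        detect_threshold=config.detect_threshold,
        substantial_threshold=config.substantial_threshold)
    labels = labels_from_results(results)
    report = validate_dmgs(dmg_table, val.beta, val.annotation, labels,
                           delta_threshold=config.dmg_delta_threshold,
                           q_threshold=config.q_threshold)
    path = outdir / "validation_report.json"
    _write_json({
        "n_tested": report.n_tested,
        "n_validated": report.n_validated,
        "validated_fraction": report.validated_fraction,
        "per_direction": report.per_direction,
        "external_overlap": report.external_overlap,
    }, path)
    return report, [path]


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order and write the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    collector = _WarningCollector()
    logging.getLogger("methylodyn").addHandler(collector)
    try:
        if config.simulate:
            cohort, sim_paths = stage_simulate(config, outdir)
            manifest.add_stage("simulate", _checksum_all(outdir, sim_paths))
            beta, sheet, timeline = cohort.beta, cohort.sheet, cohort.timeline
            atlas, annotation = cohort.atlas, cohort.annotation
            gene_sets = read_gene_sets(outdir / "inputs" / "gene_sets.gmt")
        else:
            beta = read_beta_matrix(config.beta_path)
            sheet = read_sample_sheet(config.sheet_path)
            timeline = read_therapy_timeline(config.timeline_path)
            atlas = read_atlas(config.atlas_path)
            annotation = read_probe_annotation(config.annotation_path)
            gene_sets = (read_gene_sets(config.gene_sets_path)
                         if config.gene_sets_path else None)
            manifest.add_stage("simulate", {})

        results, _, paths = stage_deconvolve(beta, atlas, sheet, config, outdir)
        manifest.add_stage("deconvolve", _checksum_all(outdir, paths))

        mvp_sets, paths = stage_mvp(beta, sheet, annotation, config, outdir)
        manifest.add_stage("mvp", _checksum_all(outdir, paths))

        _, paths = stage_cluster(beta, sheet, annotation, mvp_sets, config, outdir)
        manifest.add_stage("cluster", _checksum_all(outdir, paths))

        shift_records, paths = stage_therapy_shift(beta, sheet, timeline,
                                                   mvp_sets, config, outdir)
        manifest.add_stage("therapy_shift", _checksum_all(outdir, paths))

        if gene_sets is not None:
            paths = stage_enrich(shift_records, mvp_sets, annotation,
                                 gene_sets, config, outdir)
            manifest.add_stage("enrich", _checksum_all(outdir, paths))
        else:
            manifest.add_stage("enrich", {})

        labels = labels_from_results(results)
        dmg_table, paths = stage_dmg(beta, annotation, sheet, labels,
                                     config, outdir)
        manifest.add_stage("dmg", _checksum_all(outdir, paths))

        if config.simulate:
            _, paths = stage_validate(dmg_table, config, outdir)
            manifest.add_stage("validate", _checksum_all(outdir, paths))
        else:
            manifest.add_stage("validate", {})
    except Exception as exc:
        manifest.warnings.extend(collector.messages)
        manifest.warnings.append(f"run aborted: {exc}")
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(outdir / "manifest.json")
        raise
    finally:
        logging.getLogger("methylodyn").removeHandler(collector)
    manifest.warnings.extend(collector.messages)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
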