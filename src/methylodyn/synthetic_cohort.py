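"""Synthetic longitudinal cfDNA methylation cohorts with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: each plasma sample is a mixture of cell-type methylation profiles
dominated by hematopoietic lineages, a minority of samples carry a
prostate/tumour fraction, a set of therapy-responsive probes shift
transiently during drug windows, and tumour DMGs are planted in the
prostate profile so their signal scales with tumour fraction. Measurement
noise is beta-distributed around the mixture mean, which keeps observed
values on the β-value support without clipping artefacts.

All randomness flows from a single seed through named `SeedSequence`
children (atlas, design, planting, noise, gene sets), so two runs at the
same seed are bit-identical and a paired cohort with a different
``noise_seed`` shares every design/planting choice but draws fresh noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    BetaMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    ReferenceAtlas,
    SampleRecord,
    SampleSheet,
    TherapyTimeline,
    TherapyWindow,
)

#: Default cell types; "prostate" is the tumour tissue of interest, the rest
#: are the hematopoietic lineages that dominate plasma cfDNA.
DEFAULT_CELL_TYPES = (
    "prostate", "neutrophil", "monocyte", "nk_cell",
    "b_cell", "cd4_t_cell", "cd8_t_cell", "erythroblast",
)

#: Relative contributions of the hematopoietic lineages to tumour-free cfDNA.
HEMATOPOIETIC_WEIGHTS = {
    "neutrophil": 0.35, "monocyte": 0.20, "nk_cell": 0.05, "b_cell": 0.08,
    "cd4_t_cell": 0.12, "cd8_t_cell": 0.10, "erythroblast": 0.10,
}

_MEAN_CLIP = 1e-3  # mixture means are kept inside (0, 1) for beta noise


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design: 9 subjects sampled at 4–6 timepoints
    every 4 months (48 samples), 20,000 probes, 8 reference cell types with
    200 marker probes each, beta noise with precision 50, 300 transient
    therapy-shift probes of Δβ = 0.2, and 100 hyper- + 100 hypomethylated
    tumour genes of Δβ = 0.3 planted in the prostate profile.
    """

    n_subjects: int = 9
    min_timepoints: int = 4
    max_timepoints: int = 6
    months_between_timepoints: float = 4.0
    n_probes: int = 20_000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 200
    noise_precision: float | None = 50.0  # None disables noise
    dirichlet_concentration: float = 100.0
    prostate_fraction_schedule: Mapping[str, Sequence[float]] | None = None
    therapy_windows: Sequence[TherapyWindow] | None = None
    n_shift_probes: int = 300
    shift_delta: float = 0.2
    shift_transient: bool = True
    n_dmg_hyper: int = 100
    n_dmg_hypo: int = 100
    dmg_delta: float = 0.3
    probes_per_gene: int = 3
    seed: int = 0
    noise_seed: int | None = None  # defaults to `seed`; set for paired cohorts

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be positive")
        if not (3 <= self.min_timepoints <= self.max_timepoints):
            raise SimulationError("need 3 ≤ min_timepoints ≤ max_timepoints")
        if len(self.cell_types) < 2:
            raise SimulationError("need at least 2 cell types")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise SimulationError("duplicate cell-type names")
        if self.markers_per_type < 1 or self.probes_per_gene < 1:
            raise SimulationError("marker and gene probe counts must be positive")
        if self.n_marker_probes > self.n_probes:
            raise SimulationError(
                f"n_probes={self.n_probes} too small to host "
                f"{self.n_marker_probes} marker probes")
        for name, delta in (("shift_delta", self.shift_delta),
                            ("dmg_delta", self.dmg_delta)):
            if not (0.0 < delta < 1.0):
                raise SimulationError(f"{name} must lie in (0, 1)")
        if self.noise_precision is not None and not math.isinf(self.noise_precision):
            if self.noise_precision <= 0:
                raise SimulationError("noise_precision must be positive")

    @property
    def n_marker_probes(self) -> int:
        return len(self.cell_types) * self.markers_per_type

    @property
    def effective_noise_seed(self) -> int:
        return self.seed if self.noise_seed is None else self.noise_seed


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    fractions: pd.DataFrame      # samples × cell types, rows sum to 1
    expected_beta: pd.DataFrame  # probes × samples pre-noise mixture means
    profiles: pd.DataFrame       # cell types × probes (post-planting)
    shifts: pd.DataFrame         # probe_id, subject_id, therapy_class, start,
                                 # end, direction, archetype, base_beta
    dmgs: pd.DataFrame           # gene, direction

    def summary_dict(self) -> dict:
        """JSON-serialisable ground truth (the large matrices excluded)."""
        return {
            "fractions": {s: {c: float(v) for c, v in row.items()}
                          for s, row in self.fractions.iterrows()},
            "shifts": self.shifts.to_dict(orient="records"),
            "dmgs": self.dmgs.to_dict(orient="records"),
        }


@dataclass
class Cohort:
    """One generated cohort: all pipeline inputs plus ground truth."""

    beta: BetaMatrix
    sheet: SampleSheet
    timeline: TherapyTimeline
    atlas: ReferenceAtlas
    annotation: ProbeAnnotation
    truth: GroundTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(stream,)))


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def generate_atlas(config: SimulationConfig) -> ReferenceAtlas:
    """Build a reference atlas with discriminative marker blocks.

    Each cell type receives ``markers_per_type`` probes that are
    near-unmethylated (β ≈ 0.1) in itself and near-methylated (β ≈ 0.9) in
    every other type, giving a marker contrast of at least 0.7.
    Deterministic under the config seed.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    k = len(config.cell_types)
    m = config.markers_per_type
    probes = _probe_ids(config.n_probes)[: k * m]
    profiles = np.empty((k, k * m))
    for t in range(k):
        block = slice(t * m, (t + 1) * m)
        profiles[:, block] = rng.uniform(0.85, 0.95, size=(k, m))
        profiles[t, block] = rng.uniform(0.05, 0.15, size=m)
    frame = pd.DataFrame(profiles, index=list(config.cell_types), columns=probes)
    prostate = "prostate" if "prostate" in config.cell_types else None
    return ReferenceAtlas(frame, prostate_name=prostate)


# ---------------------------------------------------------------------------
# Cohort design helpers
# ---------------------------------------------------------------------------

def _timepoint_counts(config: SimulationConfig,
                      rng: np.random.Generator) -> list[int]:
    # The study design: 5×6 + 2×5 + 2×4 timepoints = 48 samples.
    if (config.n_subjects, config.min_timepoints, config.max_timepoints) == (9, 4, 6):
        return [6, 6, 6, 6, 6, 5, 5, 4, 4]
    return list(rng.integers(config.min_timepoints,
                             config.max_timepoints + 1,
                             size=config.n_subjects))


#: Curated per-subject tumour-fraction trajectories emulating the study's
#: composition: 16/48 samples with detectable prostate content (≥ 0.03)
#: across 6 subjects, 10 of them substantial (≥ 0.10) across 4 subjects,
#: maximum fraction 0.49.
_DEFAULT_SCHEDULE_9 = {
    "S001": [0.20, 0.49, 0.35, 0.30, 0.25, 0.15],
    "S002": [0.00, 0.05, 0.15, 0.30, 0.00, 0.00],
    "S003": [0.00, 0.00, 0.12, 0.05, 0.05, 0.00],
    "S004": [0.00, 0.10, 0.00, 0.00, 0.00, 0.04],
    "S005": [0.00, 0.00, 0.05, 0.00, 0.00, 0.00],
    "S006": [0.00, 0.00, 0.00, 0.06, 0.00],
    "S007": [0.00, 0.00, 0.00, 0.00, 0.00],
    "S008": [0.00, 0.00, 0.00, 0.00],
    "S009": [0.00, 0.00, 0.00, 0.00],
}


def _default_schedule(subjects: Sequence[str],
                      counts: Sequence[int]) -> dict[str, list[float]]:
    if list(subjects) == list(_DEFAULT_SCHEDULE_9) and \
            [len(v) for v in _DEFAULT_SCHEDULE_9.values()] == list(counts):
        return {k: list(v) for k, v in _DEFAULT_SCHEDULE_9.items()}
    return {s: [0.0] * c for s, c in zip(subjects, counts)}


def default_therapy_windows(subjects: Sequence[str],
                            counts: Sequence[int]) -> list[TherapyWindow]:
    """Default therapy timeline.

    Every subject receives a taxane window positioned so a baseline sample
    precedes it, at least two samples fall inside it, and one sample
    follows cessation (enabling transience assessment). The second subject
    additionally starts an open-ended AR inhibitor, and the fifth receives
    an AR inhibitor overlapping the taxane window (simultaneous therapies,
    as happened for two study subjects).
    """
    windows = []
    for i, (subject, c) in enumerate(zip(subjects, counts)):
        if c >= 5:
            windows.append(TherapyWindow(subject, "TAXANE", 5.0, 13.0))
        else:
            windows.append(TherapyWindow(subject, "TAXANE", 2.0, 9.0))
        if c >= 6:
            if i == 1:
                windows.append(TherapyWindow(subject, "AR_INHIBITOR", 17.0, math.inf))
            elif i == 4:
                windows.append(TherapyWindow(subject, "AR_INHIBITOR", 9.0, 13.0))
    return windows


def _build_annotation(config: SimulationConfig) -> tuple[ProbeAnnotation, dict[str, list[str]]]:
    """Assign genes to probe blocks after the marker block.

    Each gene owns ``probes_per_gene`` consecutive probes with regulatory
    region classes (TSS200/TSS1500/5UTR cycling); marker and leftover
    probes are intergenic.
    """
    probes = _probe_ids(config.n_probes)
    n_marker = config.n_marker_probes
    n_gene_probes = config.n_probes - n_marker
    n_genes = n_gene_probes // config.probes_per_gene
    regions_cycle = ("TSS200", "TSS1500", "5UTR")
    rows = []
    gene_probes: dict[str, list[str]] = {}
    chrom = lambda i: f"chr{(i % 22) + 1}"
    for i in range(n_marker):
        rows.append((probes[i], None, "INTERGENIC", chrom(i)))
    idx = n_marker
    for g in range(n_genes):
        gene = f"GENE{g + 1:05d}"
        gene_probes[gene] = []
        for j in range(config.probes_per_gene):
            p = probes[idx]
            rows.append((p, gene, regions_cycle[j % 3], chrom(idx)))
            gene_probes[gene].append(p)
            idx += 1
    while idx < config.n_probes:
        rows.append((probes[idx], None, "INTERGENIC", chrom(idx)))
        idx += 1
    table = pd.DataFrame(rows, columns=["probe_id", "gene", "region", "chromosome"])
    return ProbeAnnotation(table), gene_probes


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one cohort under the configured study conditions.

    Each sample's expected β is the fraction-weighted mixture of cell-type
    profiles; therapy-shift effects are added to the mixture mean inside
    (or from, for persistent shifts) the assigned therapy window; observed
    β is drawn from Beta(mean·ν, (1−mean)·ν) with ν = ``noise_precision``.
    """
    config.validate()
    probes = _probe_ids(config.n_probes)
    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]

    # --- design: timepoints, samples, fractions ---------------------------
    design_rng = _rng(config.seed, 1)
    counts = _timepoint_counts(config, design_rng)
    schedule = (dict(config.prostate_fraction_schedule)
                if config.prostate_fraction_schedule is not None
                else _default_schedule(subjects, counts))
    for s in schedule:
        if s not in subjects:
            raise SimulationError(f"prostate schedule references unknown subject {s!r}")
    records: list[SampleRecord] = []
    for subject, c in zip(subjects, counts):
        sched = schedule.get(subject, [0.0] * c)
        if len(sched) != c:
            raise SimulationError(
                f"schedule for {subject} has {len(sched)} entries, expected {c}")
        for j in range(c):
            label = "BL" if j == 0 else f"FU{j}"
            records.append(SampleRecord(
                sample_id=f"{subject}_{label}",
                subject_id=subject,
                timepoint_label=label,
                month=j * config.months_between_timepoints,
                psa=round(float(design_rng.lognormal(2.5, 1.0)), 2),
                cfdna_conc=round(float(design_rng.lognormal(1.2, 0.6)), 2),
            ))
    sheet = SampleSheet(records)
    sample_ids = list(sheet.sample_ids())

    cell_types = list(config.cell_types)
    hema = [c for c in cell_types if c != "prostate"]
    weights = np.array([HEMATOPOIETIC_WEIGHTS.get(c, 1.0) for c in hema])
    weights = weights / weights.sum()
    fractions = pd.DataFrame(0.0, index=sample_ids, columns=cell_types)
    for subject, c in zip(subjects, counts):
        sched = schedule.get(subject, [0.0] * c)
        for rec, p in zip(sheet.records_for(subject), sched):
            base = design_rng.dirichlet(weights * config.dirichlet_concentration)
            if "prostate" in cell_types:
                fractions.loc[rec.sample_id, "prostate"] = p
                fractions.loc[rec.sample_id, hema] = (1.0 - p) * base
            else:
                fractions.loc[rec.sample_id, hema] = base

    # --- profiles: atlas markers + shared background ----------------------
    atlas = generate_atlas(config)
    bg_rng = _rng(config.seed, 9)  # background profile stream
    profiles = np.empty((len(cell_types), config.n_probes))
    n_marker = config.n_marker_probes
    profiles[:, :n_marker] = atlas.profiles.to_numpy()
    n_bg = config.n_probes - n_marker
    low = bg_rng.beta(2.0, 10.0, size=n_bg)
    high = bg_rng.beta(10.0, 2.0, size=n_bg)
    base = np.where(bg_rng.random(n_bg) < 0.5, low, high)
    profiles[:, n_marker:] = base[None, :]

    annotation, gene_probes = _build_annotation(config)
    probe_index = {p: i for i, p in enumerate(probes)}

    # --- planting: DMG genes and therapy-shift probes ---------------------
    plant_rng = _rng(config.seed, 2)
    genes = sorted(gene_probes)
    n_dmg = config.n_dmg_hyper + config.n_dmg_hypo
    if n_dmg > len(genes):
        raise SimulationError("not enough genes to host the requested DMGs")
    dmg_rows = []
    dmg_gene_set: set[str] = set()
    if n_dmg:
        chosen = plant_rng.choice(len(genes), size=n_dmg, replace=False)
        prostate_row = cell_types.index("prostate") if "prostate" in cell_types else None
        for rank, gi in enumerate(chosen):
            gene = genes[gi]
            direction = "HYPER" if rank < config.n_dmg_hyper else "HYPO"
            dmg_gene_set.add(gene)
            for p in gene_probes[gene]:
                col = probe_index[p]
                if direction == "HYPER":
                    b = plant_rng.uniform(0.15, 0.25)
                    profiles[:, col] = b
                    if prostate_row is not None:
                        profiles[prostate_row, col] = b + config.dmg_delta
                else:
                    b = plant_rng.uniform(0.75, 0.85)
                    profiles[:, col] = b
                    if prostate_row is not None:
                        profiles[prostate_row, col] = b - config.dmg_delta
            dmg_rows.append({"gene": gene, "direction": direction})
    dmgs = pd.DataFrame(dmg_rows, columns=["gene", "direction"])

    timeline = TherapyTimeline(
        list(config.therapy_windows) if config.therapy_windows is not None
        else default_therapy_windows(subjects, counts))

    shift_rows = []
    if config.n_shift_probes:
        eligible = [p for g in genes if g not in dmg_gene_set
                    for p in gene_probes[g]]
        if config.n_shift_probes > len(eligible):
            raise SimulationError("not enough non-DMG gene probes for shifts")
        windows = list(timeline.windows)
        if not windows:
            raise SimulationError("shift probes requested but no therapy windows")
        chosen = plant_rng.choice(len(eligible), size=config.n_shift_probes,
                                  replace=False)
        for p_i in chosen:
            probe = eligible[p_i]
            w = windows[int(plant_rng.integers(len(windows)))]
            up = bool(plant_rng.integers(2))
            # gain-of-methylation shifts start near-unmethylated and vice
            # versa: the canonical promoter patterns, and the regime where
            # beta noise is tight enough for single-sample transience calls.
            base_beta = (plant_rng.uniform(0.05, 0.15) if up
                         else plant_rng.uniform(0.85, 0.95))
            col = probe_index[probe]
            profiles[:, col] = base_beta
            archetype = ("pulse_up" if up else "pulse_down") \
                if config.shift_transient else ("step_up" if up else "step_down")
            shift_rows.append({
                "probe_id": probe, "subject_id": w.subject_id,
                "therapy_class": w.therapy_class,
                "start_month": w.start_month,
                "end_month": (None if w.is_ongoing else w.end_month),
                "direction": "HYPER" if up else "HYPO",
                "archetype": archetype, "base_beta": base_beta,
            })
    shifts = pd.DataFrame(shift_rows, columns=[
        "probe_id", "subject_id", "therapy_class", "start_month", "end_month",
        "direction", "archetype", "base_beta"])

    # --- expected mixture + shift effects ---------------------------------
    expected = fractions.to_numpy() @ profiles  # samples × probes
    month_of = {r.sample_id: r.month for r in sheet.records}
    subject_of = {r.sample_id: r.subject_id for r in sheet.records}
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    for row in shift_rows:
        col = probe_index[row["probe_id"]]
        delta = config.shift_delta if row["direction"] == "HYPER" else -config.shift_delta
        end = math.inf if row["end_month"] is None else row["end_month"]
        transient = row["archetype"].startswith("pulse")
        for s in sample_ids:
            if subject_of[s] != row["subject_id"]:
                continue
            m = month_of[s]
            active = (row["start_month"] <= m <= end) if transient \
                else (m >= row["start_month"])
            if active:
                expected[sample_pos[s], col] += delta
    np.clip(expected, _MEAN_CLIP, 1.0 - _MEAN_CLIP, out=expected)

    # --- observation noise -------------------------------------------------
    nu = config.noise_precision
    if nu is None or math.isinf(nu):
        observed = expected.copy()
    else:
        noise_rng = _rng(config.effective_noise_seed, 3)
        observed = noise_rng.beta(expected * nu, (1.0 - expected) * nu)
        np.clip(observed, 0.0, 1.0, out=observed)

    beta = BetaMatrix(pd.DataFrame(observed.T, index=probes, columns=sample_ids))
    truth = GroundTruth(
        fractions=fractions,
        expected_beta=pd.DataFrame(expected.T, index=probes, columns=sample_ids),
        profiles=pd.DataFrame(profiles, index=cell_types, columns=probes),
        shifts=shifts,
        dmgs=dmgs,
    )
    return Cohort(beta=beta, sheet=sheet, timeline=timeline, atlas=atlas,
                  annotation=annotation, truth=truth)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(annotation: ProbeAnnotation, truth: GroundTruth,
                       seed: int = 0, n_random_sets: int = 6,
                       random_set_size: int = 50) -> GeneSetCollection:
    """Gene sets for enrichment testing against the synthetic cohort.

    ``IMMUNE_RESPONSE`` is enriched for genes carrying planted therapy-shift
    probes (mirroring the immune-pathway signal of therapy-responsive
    probes); the remaining sets are random draws from the gene universe.
    """
    rng = _rng(seed, 4)
    universe = sorted(annotation.genes())
    shift_genes = sorted(annotation.genes_for_probes(truth.shifts["probe_id"]))
    sets: dict[str, list[str]] = {}
    if shift_genes:
        take = max(1, int(0.6 * len(shift_genes)))
        members = list(rng.choice(shift_genes, size=take, replace=False))
        pad = rng.choice(universe, size=max(0, random_set_size - len(members)),
                         replace=False)
        sets["IMMUNE_RESPONSE"] = sorted(set(members) | set(pad))
    for i in range(n_random_sets):
        members = rng.choice(universe, size=min(random_set_size, len(universe)),
                             replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Focused benchmarks
# ---------------------------------------------------------------------------

def generate_deconvolution_benchmark(
        seed: int = 0,
        planted_fractions: Sequence[float] = (0.0, 0.05, 0.15, 0.30),
        n_per_fraction: int = 12,
        noise_precision: float | None = 50.0,
        config: SimulationConfig | None = None,
) -> tuple[BetaMatrix, ReferenceAtlas, pd.DataFrame]:
    """Marker-probe mixtures at known tumour fractions.

    Returns (β over marker probes, atlas, true fraction matrix). Samples
    cycle through ``planted_fractions``; the non-tumour remainder is a
    Dirichlet draw around the hematopoietic base composition.
    """
    config = config or SimulationConfig(seed=seed)
    config = replace(config, seed=seed)
    atlas = generate_atlas(config)
    rng = _rng(seed, 5)
    cell_types = list(atlas.cell_types)
    hema = [c for c in cell_types if c != atlas.prostate_name]
    weights = np.array([HEMATOPOIETIC_WEIGHTS.get(c, 1.0) for c in hema])
    weights = weights / weights.sum()
    samples, rows = [], []
    for i in range(n_per_fraction * len(planted_fractions)):
        p = planted_fractions[i % len(planted_fractions)]
        base = rng.dirichlet(weights * config.dirichlet_concentration)
        frac = pd.Series(0.0, index=cell_types)
        frac[atlas.prostate_name] = p
        frac[hema] = (1.0 - p) * base
        samples.append(f"MIX{i + 1:03d}")
        rows.append(frac)
    fractions = pd.DataFrame(rows, index=samples)
    expected = fractions.to_numpy() @ atlas.profiles.to_numpy()
    np.clip(expected, _MEAN_CLIP, 1.0 - _MEAN_CLIP, out=expected)
    if noise_precision is None or math.isinf(noise_precision):
        observed = expected
    else:
        observed = rng.beta(expected * noise_precision,
                            (1.0 - expected) * noise_precision)
    beta = BetaMatrix(pd.DataFrame(observed.T, index=list(atlas.marker_probes),
                                   columns=samples))
    return beta, atlas, fractions


def generate_shift_benchmark(seed: int = 0, n_shift_probes: int = 300,
                             shift_delta: float = 0.2,
                             noise_precision: float | None = 50.0,
                             transient: bool = True) -> Cohort:
    """Single-subject cohort with planted therapy-shift probes.

    Six timepoints at months 0–20; a taxane window over months 5–13 leaves
    a baseline sample (month 4), two on-therapy samples (8, 12) and a
    post-cessation sample (16) for transience assessment.
    """
    config = SimulationConfig(
        n_subjects=1, min_timepoints=6, max_timepoints=6,
        n_probes=3000, markers_per_type=10,
        noise_precision=noise_precision,
        prostate_fraction_schedule={"S001": [0.0] * 6},
        therapy_windows=[TherapyWindow("S001", "TAXANE", 5.0, 13.0)],
        n_shift_probes=n_shift_probes, shift_delta=shift_delta,
        shift_transient=transient,
        n_dmg_hyper=0, n_dmg_hypo=0, seed=seed,
    )
    return generate_cohort(config)


@dataclass
class DMGBenchmark:
    """Gene-level benchmark for differential methylation calling."""

    beta: BetaMatrix
    annotation: ProbeAnnotation
    sheet: SampleSheet
    labels: dict[str, str]       # sample → NPC / PC_SUBSTANTIAL
    plan: pd.DataFrame           # probe_id, gene, direction, base_beta


def generate_dmg_benchmark(seed: int = 0, n_genes: int = 2000,
                           n_hyper: int = 100, n_hypo: int = 100,
                           dmg_delta: float = 0.3,
                           n_pc: int = 3, n_npc: int = 30,
                           noise_precision: float | None = 50.0,
                           probes_per_gene: int = 3,
                           plan: pd.DataFrame | None = None,
                           noise_seed: int | None = None) -> DMGBenchmark:
    """Benchmark cohort where planted Δβ is the PC-vs-NPC group contrast.

    PC samples' promoter probes of planted genes are moved by ±``dmg_delta``
    relative to the shared baseline mean. Passing a previous benchmark's
    ``plan`` regenerates the same planting (genes, directions, baseline
    means) with fresh samples and noise — a paired validation cohort.
    """
    if n_hyper + n_hypo > n_genes:
        raise SimulationError("more planted DMGs than genes")
    if plan is None:
        plant_rng = _rng(seed, 6)
        genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
        directions = (["HYPER"] * n_hyper + ["HYPO"] * n_hypo
                      + ["NULL"] * (n_genes - n_hyper - n_hypo))
        order = plant_rng.permutation(n_genes)
        rows = []
        pid = 0
        for gi in range(n_genes):
            gene, direction = genes[gi], directions[order[gi]]
            for _ in range(probes_per_gene):
                if direction == "HYPER":
                    b = plant_rng.uniform(0.15, 0.35)
                elif direction == "HYPO":
                    b = plant_rng.uniform(0.65, 0.85)
                else:
                    b = plant_rng.uniform(0.10, 0.90)
                rows.append({"probe_id": f"cg{pid:08d}", "gene": gene,
                             "direction": direction, "base_beta": b})
                pid += 1
        plan = pd.DataFrame(rows)
    ann_rows = []
    regions = ("TSS200", "TSS1500", "5UTR")
    for i, rec in enumerate(plan.itertuples(index=False)):
        ann_rows.append((rec.probe_id, rec.gene, regions[i % 3],
                         f"chr{(i % 22) + 1}"))
    annotation = ProbeAnnotation(pd.DataFrame(
        ann_rows, columns=["probe_id", "gene", "region", "chromosome"]))

    records, labels = [], {}
    for j in range(n_pc):
        sid = f"SPC_T{j}"
        records.append(SampleRecord(sid, "SPC", "BL" if j == 0 else f"FU{j}",
                                    4.0 * j))
        labels[sid] = "PC_SUBSTANTIAL"
    n_npc_subjects = max(1, n_npc // 3)
    j = 0
    for k in range(n_npc):
        subj = f"SN{(k % n_npc_subjects) + 1:02d}"
        tp = k // n_npc_subjects
        sid = f"{subj}_T{tp}"
        records.append(SampleRecord(sid, subj, "BL" if tp == 0 else f"FU{tp}",
                                    4.0 * tp))
        labels[sid] = "NPC"
    # group records per subject for sheet validation order
    records.sort(key=lambda r: (r.subject_id, r.month))
    sheet = SampleSheet(records)

    sample_ids = [r.sample_id for r in records]
    base = plan["base_beta"].to_numpy()
    direction = plan["direction"].to_numpy()
    shift = np.where(direction == "HYPER", dmg_delta,
                     np.where(direction == "HYPO", -dmg_delta, 0.0))
    expected = np.empty((len(base), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        mean = base + (shift if labels[sid] != "NPC" else 0.0)
        expected[:, j] = np.clip(mean, _MEAN_CLIP, 1.0 - _MEAN_CLIP)
    nu = noise_precision
    if nu is None or math.isinf(nu):
        observed = expected
    else:
        noise_rng = _rng(seed if noise_seed is None else noise_seed, 7)
        observed = noise_rng.beta(expected * nu, (1.0 - expected) * nu)
    beta = BetaMatrix(pd.DataFrame(observed, index=list(plan["probe_id"]),
                                   columns=sample_ids))
    return DMGBenchmark(beta=beta, annotation=annotation, sheet=sheet,
                        labels=labels, plan=plan)


def generate_trajectory_benchmark(seed: int = 0, n_per_archetype: int = 20,
                                  n_timepoints: int = 6,
                                  noise_sd: float = 0.02
                                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Probe trajectories from three planted archetypes.

    Archetypes: step-up (low → high at mid-course), step-down, and a
    transient pulse. Gaussian jitter of ``noise_sd`` is added and values
    clipped to [0, 1]. Returns (probes × timepoints frame, archetype labels).
    """
    rng = _rng(seed, 8)
    t = np.arange(n_timepoints)
    mid = n_timepoints // 2
    shapes = {
        "step_up": np.where(t < mid, 0.2, 0.7),
        "step_down": np.where(t < mid, 0.7, 0.2),
        "pulse": np.where((t >= mid - 1) & (t <= mid), 0.7, 0.2),
    }
    rows, labels = [], []
    for name, shape in shapes.items():
        for i in range(n_per_archetype):
            rows.append(np.clip(shape + rng.normal(0.0, noise_sd, n_timepoints),
                                0.0, 1.0))
            labels.append(name)
    probes = [f"cg{i:08d}" for i in range(len(rows))]
    frame = pd.DataFrame(rows, index=probes,
                         columns=[f"T{j}" for j in range(n_timepoints)])
    return frame, pd.Series(labels, index=probes, name="archetype")
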