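"""Validated domain types and readers/writers for methylation-cohort artifacts.

Every tabular artifact the pipeline touches is plain text: β-value matrices
as TSV (probes as rows, samples as columns — EPIC-scale matrices are tall),
clinical tables and the reference atlas as CSV, gene sets as GMT, and
downstream reports as JSON. Loaders validate on read and reject out-of-range
or out-of-vocabulary content rather than silently coercing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of probe region classes (EPIC-manifest style).
REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "BODY", "3UTR", "INTERGENIC")

#: Promoter-proximal ("5′ regulatory") region classes.
REGULATORY_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR"})

#: Closed vocabulary of therapy classes.
THERAPY_CLASSES = ("LHRH", "TAXANE", "AR_INHIBITOR", "RADIOISOTOPE")

#: Sentinel for an open-ended therapy window.
ONGOING = math.inf


class DataValidationError(ValueError):
    """An input artifact violates a domain invariant."""


def _duplicates(values: Iterable) -> list:
    seen, dups = set(), []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

class BetaMatrix:
    """Probes × samples matrix of methylation fractions (β-values) in [0, 1].

    Missing measurements are NaN. Probe and sample identifiers must be
    unique; any non-missing value outside [0, 1] is rejected at
    construction with the offending probe and sample named.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        frame = frame.astype(float)
        dup_p = _duplicates(frame.index)
        if dup_p:
            raise DataValidationError(f"duplicate probe IDs: {dup_p}")
        dup_s = _duplicates(frame.columns)
        if dup_s:
            raise DataValidationError(f"duplicate sample IDs: {dup_s}")
        vals = frame.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = np.argwhere((vals < 0.0) | (vals > 1.0))
        if bad.size:
            i, j = bad[0]
            raise DataValidationError(
                f"β value out of [0, 1] at probe {frame.index[i]!r}, "
                f"sample {frame.columns[j]!r}: {vals[i, j]}"
            )
        self._frame = frame

    # -- accessors ----------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying probes × samples DataFrame (treat as read-only)."""
        return self._frame

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def subset(self, probes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "BetaMatrix":
        """Restrict to the given probes and/or samples (order preserved)."""
        frame = self._frame
        if probes is not None:
            missing = [p for p in probes if p not in frame.index]
            if missing:
                raise DataValidationError(f"probes not in matrix: {missing[:10]}")
            frame = frame.loc[list(probes)]
        if samples is not None:
            missing = [s for s in samples if s not in frame.columns]
            if missing:
                raise DataValidationError(f"samples not in matrix: {missing[:10]}")
            frame = frame[list(samples)]
        return BetaMatrix(frame)

    def sample_values(self, sample_id: str) -> pd.Series:
        return self._frame[sample_id]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.shape[0]} probes × {self.shape[1]} samples)"


def read_beta_matrix(path: str | Path, delimiter: str = "\t") -> BetaMatrix:
    """Read a probes × samples β TSV (first column probe IDs, header samples).

    Empty cells and "NA" are read as missing.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    dup = _duplicates(header[1:])
    if dup:
        raise DataValidationError(f"duplicate sample IDs in {path.name}: {dup}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0,
                        na_values=["", "NA"], keep_default_na=False)
    return BetaMatrix(frame)


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      delimiter: str = "\t") -> None:
    beta.frame.to_csv(path, sep=delimiter, na_rep="NA",
                      float_format="%.10g", index_label="probe_id")


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe → gene annotation, exploded to (probe, gene, region) triples.

    EPIC-style probes may map to several genes; each (probe, gene) pair
    carries exactly one region class from the closed vocabulary. Probes
    without a gene carry a missing gene and (typically) INTERGENIC region.
    """

    table: pd.DataFrame  # columns: probe_id, gene, region, chromosome

    def __post_init__(self):
        required = {"probe_id", "gene", "region", "chromosome"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataValidationError(f"annotation missing columns: {sorted(missing)}")
        bad = sorted(set(self.table["region"]) - set(REGION_CLASSES))
        if bad:
            raise DataValidationError(
                f"unknown region class(es) {bad}; allowed: {list(REGION_CLASSES)}"
            )
        with_gene = self.table.dropna(subset=["gene"])
        dup = with_gene.duplicated(subset=["probe_id", "gene"])
        if dup.any():
            pairs = with_gene.loc[dup, ["probe_id", "gene"]].values.tolist()
            raise DataValidationError(f"duplicate (probe, gene) pairs: {pairs[:10]}")

    def regulatory_probes(self) -> frozenset:
        """Probes annotated TSS1500/TSS200/5UTR for at least one gene."""
        mask = self.table["region"].isin(REGULATORY_REGIONS)
        return frozenset(self.table.loc[mask, "probe_id"])

    def genes(self) -> frozenset:
        return frozenset(self.table["gene"].dropna())

    def gene_to_probes(self, regulatory_only: bool = True) -> dict[str, list[str]]:
        """Map gene symbol → sorted probe IDs (optionally regulatory only)."""
        tab = self.table.dropna(subset=["gene"])
        if regulatory_only:
            tab = tab[tab["region"].isin(REGULATORY_REGIONS)]
        out: dict[str, list[str]] = {}
        for gene, grp in tab.groupby("gene", sort=True):
            out[str(gene)] = sorted(set(grp["probe_id"]))
        return out

    def genes_for_probes(self, probes: Iterable[str],
                         regulatory_only: bool = True) -> frozenset:
        probes = set(probes)
        tab = self.table.dropna(subset=["gene"])
        if regulatory_only:
            tab = tab[tab["region"].isin(REGULATORY_REGIONS)]
        return frozenset(tab.loc[tab["probe_id"].isin(probes), "gene"])


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation CSV.

    Columns: probe_id, gene_symbols (';'-joined, may be empty),
    region_classes (';'-joined, parallel to gene_symbols; a single value
    when no gene), chromosome.
    """
    raw = pd.read_csv(path, dtype=str, na_values=[""], keep_default_na=False)
    required = {"probe_id", "gene_symbols", "region_classes", "chromosome"}
    missing = required - set(raw.columns)
    if missing:
        raise DataValidationError(f"annotation missing columns: {sorted(missing)}")
    rows = []
    for rec in raw.itertuples(index=False):
        genes = [] if pd.isna(rec.gene_symbols) else str(rec.gene_symbols).split(";")
        regions = str(rec.region_classes).split(";")
        if genes and len(genes) != len(regions):
            raise DataValidationError(
                f"probe {rec.probe_id}: {len(genes)} genes but {len(regions)} regions"
            )
        if not genes:
            for region in regions:
                rows.append((rec.probe_id, None, region, rec.chromosome))
        else:
            for gene, region in zip(genes, regions):
                rows.append((rec.probe_id, gene, region, rec.chromosome))
    table = pd.DataFrame(rows, columns=["probe_id", "gene", "region", "chromosome"])
    return ProbeAnnotation(table)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    rows = []
    for probe, grp in annotation.table.groupby("probe_id", sort=True):
        genes = [g for g in grp["gene"] if pd.notna(g)]
        regions = list(grp["region"])
        rows.append({
            "probe_id": probe,
            "gene_symbols": ";".join(genes),
            "region_classes": ";".join(regions),
            "chromosome": grp["chromosome"].iloc[0],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """One plasma sample: subject, timepoint label and clinical covariates."""

    sample_id: str
    subject_id: str
    timepoint_label: str
    month: float
    psa: float | None = None
    cfdna_conc: float | None = None

    def __post_init__(self):
        if self.month < 0:
            raise DataValidationError(
                f"sample {self.sample_id}: negative month {self.month}")
        for name in ("psa", "cfdna_conc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DataValidationError(
                    f"sample {self.sample_id}: negative {name} {v}")


class SampleSheet:
    """Ordered collection of samples grouped by subject.

    Within a subject, months since baseline must be strictly increasing in
    the given record order and timepoint labels must be unique.
    """

    def __init__(self, records: Sequence[SampleRecord]):
        records = tuple(records)
        dup = _duplicates(r.sample_id for r in records)
        if dup:
            raise DataValidationError(f"duplicate sample IDs: {dup}")
        by_subject: dict[str, list[SampleRecord]] = {}
        for r in records:
            by_subject.setdefault(r.subject_id, []).append(r)
        for subject, recs in by_subject.items():
            months = [r.month for r in recs]
            if any(b <= a for a, b in zip(months, months[1:])):
                raise DataValidationError(
                    f"subject {subject}: months not strictly increasing: {months}")
            dup_tp = _duplicates(r.timepoint_label for r in recs)
            if dup_tp:
                raise DataValidationError(
                    f"subject {subject}: duplicate timepoint labels: {dup_tp}")
        self._records = records
        self._by_subject = {k: tuple(v) for k, v in by_subject.items()}

    @property
    def records(self) -> tuple[SampleRecord, ...]:
        return self._records

    def subjects(self) -> tuple[str, ...]:
        return tuple(self._by_subject)

    def records_for(self, subject_id: str) -> tuple[SampleRecord, ...]:
        if subject_id not in self._by_subject:
            raise KeyError(f"unknown subject {subject_id!r}")
        return self._by_subject[subject_id]

    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self._records)

    def subject_of(self, sample_id: str) -> str:
        for r in self._records:
            if r.sample_id == sample_id:
                return r.subject_id
        raise KeyError(f"unknown sample {sample_id!r}")

    def __len__(self) -> int:
        return len(self._records)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample_id": r.sample_id,
            "subject_id": r.subject_id,
            "timepoint_label": r.timepoint_label,
            "month": r.month,
            "psa": r.psa,
            "cfdna_conc": r.cfdna_conc,
        } for r in self._records])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample-sheet CSV (sample_id, subject_id, timepoint_label, month
    [, psa, cfdna_conc]); records are grouped by subject in file order."""
    raw = pd.read_csv(path, na_values=[""], keep_default_na=False)
    required = {"sample_id", "subject_id", "timepoint_label", "month"}
    missing = required - set(raw.columns)
    if missing:
        raise DataValidationError(f"sample sheet missing columns: {sorted(missing)}")

    def opt(rec, col):
        if col not in raw.columns:
            return None
        v = getattr(rec, col)
        return None if (v is None or (isinstance(v, float) and math.isnan(v))
                        or v == "") else float(v)

    records = [SampleRecord(
        sample_id=str(rec.sample_id),
        subject_id=str(rec.subject_id),
        timepoint_label=str(rec.timepoint_label),
        month=float(rec.month),
        psa=opt(rec, "psa"),
        cfdna_conc=opt(rec, "cfdna_conc"),
    ) for rec in raw.itertuples(index=False)]
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Therapy timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TherapyWindow:
    """One therapy administration interval for one subject (months)."""

    subject_id: str
    therapy_class: str
    start_month: float
    end_month: float  # ONGOING (inf) when open-ended

    def __post_init__(self):
        if self.therapy_class not in THERAPY_CLASSES:
            raise DataValidationError(
                f"unknown therapy class {self.therapy_class!r}; "
                f"allowed: {list(THERAPY_CLASSES)}")
        if self.start_month < 0:
            raise DataValidationError(
                f"{self.subject_id}/{self.therapy_class}: negative start month")
        if self.end_month < self.start_month:
            raise DataValidationError(
                f"{self.subject_id}/{self.therapy_class}: end before start")

    @property
    def is_ongoing(self) -> bool:
        return math.isinf(self.end_month)

    def covers(self, month: float) -> bool:
        return self.start_month <= month <= self.end_month

    def overlaps(self, other: "TherapyWindow") -> bool:
        return (self.start_month <= other.end_month
                and other.start_month <= self.end_month)


class TherapyTimeline:
    """All therapy windows across the cohort."""

    def __init__(self, windows: Sequence[TherapyWindow]):
        self._windows = tuple(windows)

    @property
    def windows(self) -> tuple[TherapyWindow, ...]:
        return self._windows

    def for_subject(self, subject_id: str,
                    therapy_class: str | None = None) -> tuple[TherapyWindow, ...]:
        out = [w for w in self._windows if w.subject_id == subject_id]
        if therapy_class is not None:
            out = [w for w in out if w.therapy_class == therapy_class]
        return tuple(out)

    def simultaneous_therapies(self, subject_id: str) -> bool:
        """True if the subject has overlapping windows of distinct classes."""
        ws = self.for_subject(subject_id)
        return any(a.overlaps(b) for i, a in enumerate(ws) for b in ws[i + 1:]
                   if a.therapy_class != b.therapy_class)

    def __len__(self) -> int:
        return len(self._windows)


def read_therapy_timeline(path: str | Path) -> TherapyTimeline:
    """Read a CSV with columns subject_id, therapy_class, start_month,
    end_month; end_month "ongoing" marks an open-ended window."""
    raw = pd.read_csv(path, dtype=str, na_values=[""], keep_default_na=False)
    required = {"subject_id", "therapy_class", "start_month", "end_month"}
    missing = required - set(raw.columns)
    if missing:
        raise DataValidationError(f"therapy timeline missing columns: {sorted(missing)}")
    windows = []
    for rec in raw.itertuples(index=False):
        end = str(rec.end_month).strip().lower()
        end_month = ONGOING if end == "ongoing" else float(rec.end_month)
        windows.append(TherapyWindow(
            subject_id=str(rec.subject_id),
            therapy_class=str(rec.therapy_class),
            start_month=float(rec.start_month),
            end_month=end_month,
        ))
    return TherapyTimeline(windows)


def write_therapy_timeline(timeline: TherapyTimeline, path: str | Path) -> None:
    rows = [{
        "subject_id": w.subject_id,
        "therapy_class": w.therapy_class,
        "start_month": w.start_month,
        "end_month": "ongoing" if w.is_ongoing else w.end_month,
    } for w in timeline.windows]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# ReferenceAtlas
# ---------------------------------------------------------------------------

class ReferenceAtlas:
    """Cell-type × marker-probe reference β profiles for deconvolution.

    One cell type may be designated as the tumour tissue of interest
    (``prostate_name``); its estimated fraction drives PC/NPC labelling.
    """

    def __init__(self, profiles: pd.DataFrame, prostate_name: str | None = "prostate"):
        profiles = profiles.copy().astype(float)
        profiles.index = profiles.index.astype(str)
        profiles.columns = profiles.columns.astype(str)
        dup_t = _duplicates(profiles.index)
        if dup_t:
            raise DataValidationError(f"duplicate cell-type names: {dup_t}")
        dup_p = _duplicates(profiles.columns)
        if dup_p:
            raise DataValidationError(f"duplicate marker probe IDs: {dup_p}")
        vals = profiles.to_numpy()
        if np.isnan(vals).any():
            raise DataValidationError("atlas profiles must not contain missing values")
        bad = np.argwhere((vals < 0.0) | (vals > 1.0))
        if bad.size:
            i, j = bad[0]
            raise DataValidationError(
                f"atlas β out of [0, 1] for cell type {profiles.index[i]!r}, "
                f"probe {profiles.columns[j]!r}: {vals[i, j]}")
        if prostate_name is not None and prostate_name not in profiles.index:
            prostate_name = None
        self._profiles = profiles
        self.prostate_name = prostate_name

    @property
    def profiles(self) -> pd.DataFrame:
        return self._profiles

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self._profiles.index)

    @property
    def marker_probes(self) -> tuple[str, ...]:
        return tuple(self._profiles.columns)


def read_atlas(path: str | Path, prostate_name: str | None = "prostate") -> ReferenceAtlas:
    """Read an atlas CSV (first column cell_type, remaining columns probes)."""
    frame = pd.read_csv(path, index_col=0)
    return ReferenceAtlas(frame, prostate_name=prostate_name)


def write_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    atlas.profiles.to_csv(path, index_label="cell_type", float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

class GeneSetCollection:
    """Named gene sets (deduplicated, non-empty)."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        cleaned: dict[str, frozenset] = {}
        for name, members in sets.items():
            fs = frozenset(members)
            if not fs:
                raise DataValidationError(f"gene set {name!r} is empty")
            cleaned[str(name)] = fs
        self._sets = cleaned

    @property
    def sets(self) -> dict[str, frozenset]:
        return dict(self._sets)

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self._sets))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataValidationError(
                    f"GMT line {lineno}: expected name, description and ≥1 member")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
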