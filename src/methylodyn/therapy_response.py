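"""Therapy-window methylation-shift detection and gene-set enrichment.

For each subject × therapy window, every assessed probe is compared
between the baseline sample (last sample at or before therapy start) and
the on-therapy samples (all samples inside the window); the signed change
of maximal magnitude is the probe's Δβ. A probe is shifted when
|Δβ| ≥ 0.1, classified hyper- or hypomethylated by the sign, and — when a
post-cessation sample exists — flagged transient if its methylation
returns to within the threshold of baseline. Gene-set enrichment of
shifted genes uses a one-sided hypergeometric tail with
Benjamini–Hochberg correction across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_io import (
    BetaMatrix,
    DataValidationError,
    GeneSetCollection,
    SampleSheet,
    TherapyTimeline,
    TherapyWindow,
)
from .dmg_analysis import benjamini_hochberg

logger = logging.getLogger(__name__)

SHIFT_THRESHOLD = 0.1  # |Δβ| at/above which a probe counts as shifted


@dataclass
class ShiftRecord:
    """One probe's methylation change across one therapy window."""

    subject_id: str
    probe_id: str
    therapy_class: str
    baseline_sample: str
    on_therapy_samples: tuple[str, ...]
    delta_beta: float            # signed change of maximal magnitude
    shifted: bool
    direction: str | None        # HYPER / HYPO when shifted
    transient: bool | None       # None when no post-cessation sample
    post_sample: str | None


def detect_shifts(beta, probes: Iterable[str], window: TherapyWindow,
                  sheet: SampleSheet,
                  shift_threshold: float = SHIFT_THRESHOLD) -> list[ShiftRecord]:
    """Shift records for the given probes across one therapy window.

    Baseline is the subject's last sample with month ≤ window start;
    on-therapy samples are all samples with start ≤ month ≤ end. A window
    without a baseline or without any on-therapy sample is skipped with a
    logged reason (empty result). Probes missing at baseline or at every
    on-therapy sample are skipped.
    """
    frame = beta.frame if isinstance(beta, BetaMatrix) else pd.DataFrame(beta)
    records = sheet.records_for(window.subject_id)
    baseline = None
    for r in records:
        if r.month <= window.start_month:
            baseline = r
    on = [r for r in records if window.covers(r.month)]
    post = None
    if not window.is_ongoing:
        for r in records:
            if r.month > window.end_month:
                post = r
                break
    if baseline is None or not on:
        logger.warning(
            "window %s/%s [%s, %s] skipped: %s", window.subject_id,
            window.therapy_class, window.start_month, window.end_month,
            "no baseline sample" if baseline is None else "no on-therapy sample")
        return []

    out: list[ShiftRecord] = []
    on_ids = tuple(r.sample_id for r in on)
    for probe in sorted(probes):
        if probe not in frame.index:
            continue
        b0 = frame.at[probe, baseline.sample_id]
        if pd.isna(b0):
            continue
        deltas = [(frame.at[probe, sid] - b0, sid) for sid in on_ids
                  if not pd.isna(frame.at[probe, sid])]
        if not deltas:
            continue
        delta, _ = max(deltas, key=lambda t: abs(t[0]))
        shifted = abs(delta) >= shift_threshold
        direction = None
        if shifted:
            direction = "HYPER" if delta > 0 else "HYPO"
        transient = None
        post_sample = None
        if post is not None and not pd.isna(frame.at[probe, post.sample_id]):
            post_sample = post.sample_id
            transient = bool(abs(frame.at[probe, post.sample_id] - b0)
                             < shift_threshold)
        out.append(ShiftRecord(
            subject_id=window.subject_id, probe_id=probe,
            therapy_class=window.therapy_class,
            baseline_sample=baseline.sample_id,
            on_therapy_samples=on_ids,
            delta_beta=float(delta), shifted=shifted, direction=direction,
            transient=transient, post_sample=post_sample,
        ))
    return out


@dataclass
class ShiftReport:
    """Shift proportions per subject × therapy class."""

    table: pd.DataFrame  # subject_id, therapy_class, n_assessed,
                         # prop_shifted, prop_hyper, prop_hypo,
                         # prop_transient, simultaneous_therapies

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def summarize_shifts(records: Sequence[ShiftRecord],
                     timeline: TherapyTimeline) -> ShiftReport:
    """Aggregate shift records into per-(subject, therapy-class) proportions.

    ``prop_hyper``/``prop_hypo`` are fractions of assessed probes (so they
    sum to ``prop_shifted``); ``prop_transient`` is the fraction of shifted
    probes with a defined transience flag that returned to baseline. The
    simultaneous-therapies flag marks subjects whose windows of distinct
    classes overlap in months, where attribution to one drug is impossible.
    """
    rows = []
    keys = sorted({(r.subject_id, r.therapy_class) for r in records})
    for subject, therapy in keys:
        grp = [r for r in records
               if r.subject_id == subject and r.therapy_class == therapy]
        n = len(grp)
        n_shift = sum(r.shifted for r in grp)
        n_hyper = sum(r.direction == "HYPER" for r in grp)
        n_hypo = sum(r.direction == "HYPO" for r in grp)
        shifted_defined = [r for r in grp if r.shifted and r.transient is not None]
        prop_transient = (sum(r.transient for r in shifted_defined)
                          / len(shifted_defined)) if shifted_defined else None
        rows.append({
            "subject_id": subject, "therapy_class": therapy,
            "n_assessed": n,
            "prop_shifted": n_shift / n if n else 0.0,
            "prop_hyper": n_hyper / n if n else 0.0,
            "prop_hypo": n_hypo / n if n else 0.0,
            "prop_transient": prop_transient,
            "simultaneous_therapies": timeline.simultaneous_therapies(subject),
        })
    columns = ["subject_id", "therapy_class", "n_assessed", "prop_shifted",
               "prop_hyper", "prop_hypo", "prop_transient",
               "simultaneous_therapies"]
    return ShiftReport(pd.DataFrame(rows, columns=columns))


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int          # |set ∩ universe|
    foreground_size: int
    universe_size: int
    p: float
    q: float
    significant: bool


def enrich_gene_sets(foreground_genes: Iterable[str],
                     universe_genes: Iterable[str],
                     sets: GeneSetCollection,
                     q_threshold: float = 0.05) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per gene set.

    Sets are intersected with the universe; p = P(X ≥ overlap) for X
    hypergeometric(universe, set∩universe, foreground); BH across sets.
    """
    universe = frozenset(universe_genes)
    if not universe:
        raise DataValidationError("empty gene universe")
    foreground = frozenset(foreground_genes)
    stray = foreground - universe
    if stray:
        raise DataValidationError(
            f"foreground genes outside universe: {sorted(stray)[:10]}")
    N, n_fg = len(universe), len(foreground)
    names = sets.names()
    results = []
    pvals = []
    for name in names:
        members = sets[name] & universe
        k = len(members & foreground)
        s = len(members)
        p = float(hypergeom.sf(k - 1, N, s, n_fg)) if s else 1.0
        pvals.append(p)
        results.append((name, k, s))
    qvals = benjamini_hochberg(pvals) if pvals else []
    out = []
    for (name, k, s), p, q in zip(results, pvals, qvals):
        out.append(EnrichmentResult(
            set_name=name, overlap=k, set_size=s, foreground_size=n_fg,
            universe_size=N, p=p, q=float(q), significant=bool(q < q_threshold)))
    return out
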