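"""Differentially methylated gene (DMG) calling between PC and NPC samples.

Gene-level methylation is the mean β over a gene's 5′ regulatory probes.
For each discovery subject with at least two substantial-prostate-content
samples, candidate genes (those hit by the subject's promoter MVPs, or an
explicit list) are tested between the subject's PC samples and all NPC
samples cohort-wide — the POOLED comparison that defines DMG status at
|Δβ| ≥ 0.1 and BH-adjusted p < 0.05 — with the subject's own NPC samples
reported descriptively when available (WITHIN_SUBJECT). Two-group testing
auto-selects Welch's t when both groups look normal (Shapiro–Wilk) and the
exact/asymptotic Mann–Whitney U otherwise. Validation re-applies the same
criteria, requiring the same direction, in an independent cohort;
histological stages are compared with Kruskal–Wallis plus Dunn's post hoc.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BetaMatrix, DataValidationError, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

DELTA_THRESHOLD = 0.1   # gene-level |Δβ| required for a DMG call
Q_THRESHOLD = 0.05      # BH-adjusted significance level

LABEL_SUBSTANTIAL = "PC_SUBSTANTIAL"
LABEL_NPC = "NPC"


class AnalysisError(ValueError):
    """Input does not support the requested analysis."""


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def gene_beta(beta, annotation: ProbeAnnotation,
              genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample gene-level β: mean over the gene's regulatory probes.

    Missing probe values are skipped per sample. Requesting a gene with no
    regulatory probe present in the matrix is an error.
    """
    frame = beta.frame if isinstance(beta, BetaMatrix) else pd.DataFrame(beta)
    g2p = annotation.gene_to_probes(regulatory_only=True)
    if genes is None:
        genes = sorted(g2p)
    rows = {}
    for gene in genes:
        probes = [p for p in g2p.get(gene, ()) if p in frame.index]
        if not probes:
            raise AnalysisError(
                f"gene {gene!r} has no regulatory probe in the matrix")
        rows[gene] = frame.loc[probes].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    return out


@dataclass
class TestResult:
    test_name: str   # WELCH_T or MANN_WHITNEY
    statistic: float
    p: float


def two_group_test(x, y, method: str = "auto") -> TestResult:
    """Unpaired two-group test: Welch's t or two-sided Mann–Whitney U.

    ``auto`` uses Welch's t when both groups have n ≥ 4 and pass
    Shapiro–Wilk normality at α = 0.05, otherwise Mann–Whitney (exact when
    min(n) ≤ 8 and the pooled values carry no ties, else the tie-corrected
    normal approximation). Groups of 3 go to the rank test regardless:
    Shapiro–Wilk has essentially no power at n = 3, so the normality gate
    is vacuous there, and Welch's df estimate collapses to ≈ 2, making the
    exact rank test both better calibrated and better powered.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("each group needs at least 2 values")
    if method not in ("auto", "welch_t", "mann_whitney"):
        raise AnalysisError(f"unknown method {method!r}")
    if method == "auto":
        use_welch = False
        if len(x) >= 4 and len(y) >= 4:
            # Shapiro-Wilk is undefined for constant input; treat as non-normal
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                use_welch = (stats.shapiro(x).pvalue > 0.05
                             and stats.shapiro(y).pvalue > 0.05)
        method = "welch_t" if use_welch else "mann_whitney"
    if method == "welch_t":
        res = stats.ttest_ind(x, y, equal_var=False)
        return TestResult("WELCH_T", float(res.statistic), float(res.pvalue))
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:  # all values identical: no evidence either way
        return TestResult("MANN_WHITNEY", float(len(x) * len(y) / 2), 1.0)
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(x), len(y)) <= 8) and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return TestResult("MANN_WHITNEY", float(res.statistic), float(res.pvalue))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# DMG calling
# ---------------------------------------------------------------------------

@dataclass
class DMGTable:
    """Per-subject DMG records plus union/uniqueness summary."""

    records: pd.DataFrame   # subject_id, gene, mean_pc, mean_npc, delta_beta,
                            # direction, test_name, p, q, called,
                            # within_delta, within_p
    per_subject: dict[str, list[str]]  # subject → called genes
    summary: dict

    def called(self) -> pd.DataFrame:
        return self.records[self.records["called"]]


def _uniqueness(records: pd.DataFrame, direction: str) -> float | None:
    calls = records[(records["called"]) & (records["direction"] == direction)]
    genes = calls["gene"].unique()
    if len(genes) == 0:
        return None
    counts = calls.groupby("gene")["subject_id"].nunique()
    return float((counts == 1).sum() / len(genes))


def call_dmgs(beta, annotation: ProbeAnnotation, sheet: SampleSheet,
              sample_labels: Mapping[str, str], *,
              delta_threshold: float = DELTA_THRESHOLD,
              q_threshold: float = Q_THRESHOLD,
              mvp_fraction: float = 0.05,
              candidate_genes: Sequence[str] | None = None,
              test_method: str = "auto") -> DMGTable:
    """Call DMGs for every subject with ≥ 2 substantial-PC samples.

    The POOLED comparison (subject's PC samples vs all NPC samples
    cohort-wide) with |Δβ| ≥ ``delta_threshold`` and BH q < ``q_threshold``
    (BH within subject, across that subject's candidate genes) defines DMG
    status; the within-subject comparison against the subject's own NPC
    samples is reported descriptively when group sizes permit. When
    ``candidate_genes`` is not given, each subject's candidates are the
    genes hit by its top-``mvp_fraction`` promoter MVPs.
    """
    from .temporal_dynamics import compute_probe_sd, select_mvps

    frame = beta.frame if isinstance(beta, BetaMatrix) else pd.DataFrame(beta)
    labels = dict(sample_labels)
    npc_all = [s for s in frame.columns if labels.get(s) == LABEL_NPC]
    if len(npc_all) < 2:
        raise AnalysisError("need ≥ 2 NPC samples cohort-wide")
    pc_by_subject: dict[str, list[str]] = {}
    for r in sheet.records:
        if labels.get(r.sample_id) == LABEL_SUBSTANTIAL:
            pc_by_subject.setdefault(r.subject_id, []).append(r.sample_id)
    eligible = {s: pcs for s, pcs in pc_by_subject.items() if len(pcs) >= 2}
    skipped = sorted(set(pc_by_subject) - set(eligible))
    if skipped:
        logger.warning("subjects excluded from DMG calling (< 2 PC samples): %s",
                       skipped)
    if not eligible:
        raise AnalysisError("no subject with ≥ 2 substantial-PC samples")

    rows = []
    per_subject: dict[str, list[str]] = {}
    for subject in sorted(eligible):
        pc = eligible[subject]
        own_npc = [r.sample_id for r in sheet.records_for(subject)
                   if labels.get(r.sample_id) == LABEL_NPC]
        if candidate_genes is None:
            subj_samples = [r.sample_id for r in sheet.records_for(subject)
                            if r.sample_id in frame.columns]
            sds = compute_probe_sd(frame[subj_samples])
            mvps = select_mvps(sds, mvp_fraction, annotation, subject_id=subject)
            candidates = sorted(annotation.genes_for_probes(mvps.regulatory))
        else:
            candidates = sorted(candidate_genes)
        if not candidates:
            logger.warning("subject %s: no candidate genes", subject)
            continue
        gb = gene_beta(frame, annotation, candidates)
        subj_rows = []
        for gene in candidates:
            xs = gb.loc[gene, pc].dropna()
            ys = gb.loc[gene, npc_all].dropna()
            if len(xs) < 2 or len(ys) < 2:
                logger.info("subject %s gene %s skipped: group too small",
                            subject, gene)
                continue
            res = two_group_test(xs, ys, method=test_method)
            delta = float(xs.mean() - ys.mean())
            within_delta = within_p = None
            if len(own_npc) >= 2:
                ws = gb.loc[gene, own_npc].dropna()
                if len(ws) >= 2:
                    wres = two_group_test(xs, ws, method=test_method)
                    within_delta = float(xs.mean() - ws.mean())
                    within_p = wres.p
            subj_rows.append({
                "subject_id": subject, "gene": gene,
                "mean_pc": float(xs.mean()), "mean_npc": float(ys.mean()),
                "delta_beta": delta,
                "direction": "HYPER" if delta > 0 else "HYPO",
                "test_name": res.test_name, "p": res.p,
                "within_delta": within_delta, "within_p": within_p,
            })
        if not subj_rows:
            continue
        qvals = benjamini_hochberg([r["p"] for r in subj_rows])
        for r, q in zip(subj_rows, qvals):
            r["q"] = float(q)
            r["called"] = bool(abs(r["delta_beta"]) >= delta_threshold
                               and q < q_threshold)
        rows.extend(subj_rows)
        per_subject[subject] = sorted(r["gene"] for r in subj_rows if r["called"])

    columns = ["subject_id", "gene", "mean_pc", "mean_npc", "delta_beta",
               "direction", "test_name", "p", "q", "called",
               "within_delta", "within_p"]
    records = pd.DataFrame(rows, columns=columns)
    called = records[records["called"]] if len(records) else records
    union_genes = sorted(called["gene"].unique()) if len(called) else []
    n_hyper = called.loc[called["direction"] == "HYPER", "gene"].nunique() \
        if len(called) else 0
    n_hypo = called.loc[called["direction"] == "HYPO", "gene"].nunique() \
        if len(called) else 0
    summary = {
        "n_subjects_tested": len(per_subject),
        "n_dmgs_union": len(union_genes),
        "n_hyper": int(n_hyper),
        "n_hypo": int(n_hypo),
        "unique_fraction_hyper": _uniqueness(records, "HYPER") if len(records) else None,
        "unique_fraction_hypo": _uniqueness(records, "HYPO") if len(records) else None,
        "excluded_subjects": skipped,
    }
    return DMGTable(records=records, per_subject=per_subject, summary=summary)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n_tested: int
    n_validated: int
    validated_fraction: float | None
    per_direction: dict
    external_overlap: dict
    records: pd.DataFrame


def _normalise_validation_labels(labels: Mapping[str, str]) -> dict[str, str]:
    out = {}
    for sample, lab in labels.items():
        if lab in ("PC", LABEL_SUBSTANTIAL):
            out[sample] = "PC"
        elif lab == LABEL_NPC:
            out[sample] = "NPC"
        # detectable-but-not-substantial samples are left out of both groups
    return out


def validate_dmgs(dmg_table: DMGTable, validation_beta,
                  validation_annotation: ProbeAnnotation,
                  validation_labels: Mapping[str, str],
                  external_gene_lists: Mapping[str, Iterable[str]] | None = None,
                  *, delta_threshold: float = DELTA_THRESHOLD,
                  q_threshold: float = Q_THRESHOLD,
                  test_method: str = "auto") -> ValidationReport:
    """Re-test discovery DMGs in an independent PC/NPC-labelled cohort.

    A discovery (gene, direction) validates when the validation cohort
    shows the same direction with |Δβ| ≥ ``delta_threshold`` and BH
    q < ``q_threshold`` (BH across the tested genes). External gene lists
    are reported as the fraction of validated DMGs each list contains.
    """
    frame = validation_beta.frame if isinstance(validation_beta, BetaMatrix) \
        else pd.DataFrame(validation_beta)
    labels = _normalise_validation_labels(validation_labels)
    pc = [s for s in frame.columns if labels.get(s) == "PC"]
    npc = [s for s in frame.columns if labels.get(s) == "NPC"]
    if len(pc) < 2 or len(npc) < 2:
        raise AnalysisError("validation cohort needs ≥ 2 PC and ≥ 2 NPC samples")

    called = dmg_table.called()
    discovery = sorted({(r.gene, r.direction)
                        for r in called.itertuples(index=False)})
    g2p = validation_annotation.gene_to_probes(regulatory_only=True)
    testable = [(g, d) for g, d in discovery
                if any(p in frame.index for p in g2p.get(g, ()))]
    if not testable:
        logger.warning("no discovery DMG measurable in the validation cohort")
        return ValidationReport(0, 0, None, {}, {}, pd.DataFrame())

    genes = sorted({g for g, _ in testable})
    gb = gene_beta(frame, validation_annotation, genes)
    rows = []
    for gene, direction in testable:
        xs = gb.loc[gene, pc].dropna()
        ys = gb.loc[gene, npc].dropna()
        if len(xs) < 2 or len(ys) < 2:
            continue
        res = two_group_test(xs, ys, method=test_method)
        delta = float(xs.mean() - ys.mean())
        rows.append({
            "gene": gene, "discovery_direction": direction,
            "delta_beta": delta,
            "direction": "HYPER" if delta > 0 else "HYPO",
            "p": res.p,
        })
    records = pd.DataFrame(rows)
    if len(records):
        records["q"] = benjamini_hochberg(records["p"])
        records["validated"] = (
            (records["direction"] == records["discovery_direction"])
            & (records["delta_beta"].abs() >= delta_threshold)
            & (records["q"] < q_threshold))
    n_tested = len(records)
    n_validated = int(records["validated"].sum()) if n_tested else 0
    per_direction = {}
    for d in ("HYPER", "HYPO"):
        sub = records[records["discovery_direction"] == d] if n_tested else records
        per_direction[d] = {
            "n_tested": len(sub),
            "n_validated": int(sub["validated"].sum()) if len(sub) else 0,
            "validated_fraction": (float(sub["validated"].mean())
                                   if len(sub) else None),
        }
    external_overlap = {}
    if external_gene_lists:
        validated_genes = set(records.loc[records["validated"], "gene"]) \
            if n_tested else set()
        for name, members in external_gene_lists.items():
            members = set(members)
            external_overlap[name] = (
                len(validated_genes & members) / len(validated_genes)
                if validated_genes else None)
    return ValidationReport(
        n_tested=n_tested, n_validated=n_validated,
        validated_fraction=(n_validated / n_tested) if n_tested else None,
        per_direction=per_direction, external_overlap=external_overlap,
        records=records)


# ---------------------------------------------------------------------------
# Histological-stage comparison (Kruskal–Wallis + Dunn)
# ---------------------------------------------------------------------------

@dataclass
class StageComparison:
    kruskal: pd.DataFrame   # gene, statistic, p
    dunn: pd.DataFrame      # gene, group_a, group_b, z, p, q


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H statistic."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def _kw_permutation_p(groups: Sequence[np.ndarray]) -> float:
    """Exact permutation p for Kruskal–Wallis on small samples.

    Enumerates every distinct assignment of the pooled values to the group
    sizes and counts assignments with H at least as large as observed.
    """
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n > 12:
        raise AnalysisError("permutation KW limited to ≤ 12 observations")
    h_obs = _kw_statistic(groups)
    sizes = [len(g) for g in groups]
    count = total = 0

    def recurse(remaining: tuple, assigned: list):
        nonlocal count, total
        if len(assigned) == len(sizes) - 1:
            groups_perm = assigned + [np.array(remaining)]
            total += 1
            if _kw_statistic(groups_perm) >= h_obs - 1e-12:
                count += 1
            return
        size = sizes[len(assigned)]
        for idx in itertools.combinations(range(len(remaining)), size):
            chosen = np.array([remaining[i] for i in idx])
            rest = tuple(v for i, v in enumerate(remaining) if i not in idx)
            recurse(rest, assigned + [chosen])

    recurse(tuple(pooled), [])
    return count / total


def compare_stages(stage_beta: pd.DataFrame,
                   stage_labels: Mapping[str, str],
                   method: str = "asymptotic") -> StageComparison:
    """Per-gene Kruskal–Wallis across ≥ 3 stage groups, with Dunn post hoc.

    ``method="asymptotic"`` uses the chi-square approximation;
    ``method="permutation"`` enumerates the exact permutation distribution
    (small samples only). Dunn pairwise z-tests use tie-corrected pooled
    ranks, BH-adjusted across pairs within each gene.
    """
    labels = dict(stage_labels)
    groups_map: dict[str, list[str]] = {}
    for sample in stage_beta.columns:
        if sample in labels:
            groups_map.setdefault(labels[sample], []).append(sample)
    group_names = sorted(groups_map)
    if len(group_names) < 3:
        raise AnalysisError(
            "stage comparison needs ≥ 3 groups; use two_group_test for two")
    for g in group_names:
        if len(groups_map[g]) < 2:
            raise AnalysisError(f"stage group {g!r} has < 2 samples")

    kw_rows, dunn_rows = [], []
    for gene in stage_beta.index:
        series = stage_beta.loc[gene]
        groups = [series[groups_map[g]].dropna().to_numpy()
                  for g in group_names]
        if any(len(g) < 2 for g in groups):
            continue
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0.0:
            stat, p = 0.0, 1.0
        elif method == "permutation":
            stat = _kw_statistic(groups)
            p = _kw_permutation_p(groups)
        else:
            stat, p = stats.kruskal(*groups)
        kw_rows.append({"gene": gene, "statistic": float(stat), "p": float(p)})

        # Dunn pairwise z on pooled ranks with tie correction
        n = len(pooled)
        ranks = stats.rankdata(pooled)
        mean_ranks, sizes = {}, {}
        i = 0
        for gname, vals in zip(group_names, groups):
            mean_ranks[gname] = ranks[i:i + len(vals)].mean()
            sizes[gname] = len(vals)
            i += len(vals)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
        base_var = n * (n + 1) / 12.0 - tie_term
        pair_rows = []
        for a, b in itertools.combinations(group_names, 2):
            var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
            if var <= 0:
                z, p_ab = 0.0, 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var)
                p_ab = float(2.0 * stats.norm.sf(abs(z)))
            pair_rows.append({"gene": gene, "group_a": a, "group_b": b,
                              "z": float(z), "p": p_ab})
        qvals = benjamini_hochberg([r["p"] for r in pair_rows])
        for r, q in zip(pair_rows, qvals):
            r["q"] = float(q)
        dunn_rows.extend(pair_rows)

    return StageComparison(
        kruskal=pd.DataFrame(kw_rows, columns=["gene", "statistic", "p"]),
        dunn=pd.DataFrame(dunn_rows,
                          columns=["gene", "group_a", "group_b", "z", "p", "q"]))
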