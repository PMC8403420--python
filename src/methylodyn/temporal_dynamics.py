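"""Per-subject temporal variability of cfDNA methylation.

The n-of-1 workflow: per-probe temporal standard deviations over one
subject's timepoints, selection of the top-fraction most-variable probes
(MVPs, default top 5%), restriction to 5′ regulatory probes
(TSS1500/TSS200/5′UTR), a global stability summary (fraction of probes
with SD below 0.1), PCA for cohort-level QC, agglomerative clustering of
probe trajectories, and per-(cluster, gene) min/mean/max envelopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .data_io import BetaMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


class TemporalAnalysisError(ValueError):
    """Input does not support the requested temporal analysis."""


def _frame(beta) -> pd.DataFrame:
    return beta.frame if isinstance(beta, BetaMatrix) else pd.DataFrame(beta)


# ---------------------------------------------------------------------------
# Probe SDs and MVP selection
# ---------------------------------------------------------------------------

def compute_probe_sd(beta_subject, min_timepoints: int = 3) -> pd.Series:
    """Sample SD (n−1 denominator) of each probe over a subject's timepoints.

    Probes with fewer than ``min_timepoints`` non-missing values are
    excluded (and logged); a subject with fewer than ``min_timepoints``
    samples is an error.
    """
    frame = _frame(beta_subject)
    if frame.shape[1] < min_timepoints:
        raise TemporalAnalysisError(
            f"subject has {frame.shape[1]} timepoints; need ≥ {min_timepoints}")
    counts = frame.notna().sum(axis=1)
    eligible = counts >= min_timepoints
    n_excluded = int((~eligible).sum())
    if n_excluded:
        logger.info("excluding %d probes with < %d non-missing timepoints",
                    n_excluded, min_timepoints)
    return frame.loc[eligible].std(axis=1, ddof=1)


@dataclass
class MVPSet:
    """A subject's most-variable probes and their regulatory subset."""

    subject_id: str
    fraction: float
    sd: pd.Series                 # temporal SD per eligible probe
    selected: tuple[str, ...]     # top-⌈fraction·n⌉ probes by SD
    regulatory: tuple[str, ...]   # selected ∩ 5′ regulatory annotation


def select_mvps(sds: pd.Series, fraction: float = 0.05,
                annotation: ProbeAnnotation | None = None,
                subject_id: str = "") -> MVPSet:
    """Top-fraction probes by temporal SD.

    The selection count is ⌈fraction · n⌉; ties on SD break by probe-ID
    lexicographic order, making the set order-invariant.
    """
    if len(sds) == 0:
        raise TemporalAnalysisError("empty SD input")
    if not (0.0 < fraction < 1.0):
        raise TemporalAnalysisError(f"fraction must lie in (0, 1), got {fraction}")
    n_select = math.ceil(fraction * len(sds))
    order = sorted(sds.index, key=lambda p: (-sds[p], p))
    selected = tuple(order[:n_select])
    regulatory: tuple[str, ...] = ()
    if annotation is not None:
        reg = annotation.regulatory_probes()
        regulatory = tuple(p for p in selected if p in reg)
    return MVPSet(subject_id=subject_id, fraction=fraction, sd=sds,
                  selected=selected, regulatory=regulatory)


def stability_summary(sds: pd.Series, threshold: float = 0.1) -> float:
    """Fraction of probes with temporal SD strictly below ``threshold``."""
    if len(sds) == 0:
        raise TemporalAnalysisError("empty SD input")
    return float((sds < threshold).mean())


# ---------------------------------------------------------------------------
# PCA QC
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame       # samples × (PC1, PC2)
    variance_explained: tuple[float, float]


def pca_qc(beta) -> PCAResult:
    """Sample coordinates on the first two principal components.

    Missing values are mean-imputed per probe (QC only); the probe-centred
    samples × probes matrix is decomposed by SVD.
    """
    frame = _frame(beta)
    if frame.shape[1] < 3:
        raise TemporalAnalysisError("PCA needs at least 3 samples")
    X = frame.to_numpy(dtype=float).T  # samples × probes
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :2] * S[:2]
    total = float((S ** 2).sum())
    var = (float(S[0] ** 2 / total), float(S[1] ** 2 / total)) if total > 0 \
        else (0.0, 0.0)
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=frame.columns,
                                 columns=["PC1", "PC2"]),
        variance_explained=var,
    )


# ---------------------------------------------------------------------------
# Trajectory clustering
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryClustering:
    """Partition of probe trajectories into congruent clusters."""

    subject_id: str
    labels: pd.Series             # probe → cluster label (1-based)
    n_clusters: int
    cluster_means: pd.DataFrame   # cluster × timepoints mean trajectory
    silhouette: float | None      # None in the degenerate single-cluster case


def cluster_trajectories(beta_subject, k_max: int = 8,
                         standardize: bool = False,
                         subject_id: str = "") -> TrajectoryClustering:
    """Agglomerative (average-linkage, euclidean) clustering of trajectories.

    The cluster count is the k in [2, k_max] maximising the mean silhouette
    (ties favour the smaller k). If every pairwise distance is zero the
    degenerate single-cluster partition is returned. By default raw β
    trajectories are compared, so clusters separate by both level and shape;
    set ``standardize`` to z-score each probe first.
    """
    frame = _frame(beta_subject)
    if frame.shape[1] < 3:
        raise TemporalAnalysisError("clustering needs ≥ 3 timepoints")
    complete = frame.dropna(axis=0)
    n_dropped = frame.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info("dropping %d probes with missing values before clustering",
                    n_dropped)
    if complete.shape[0] < 2:
        raise TemporalAnalysisError("clustering needs ≥ 2 complete probes")
    X = complete.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=1, ddof=0, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    n = X.shape[0]
    k_max = min(k_max, n - 1)
    if pdist(X).max() == 0.0:
        labels = pd.Series(1, index=complete.index)
        means = pd.DataFrame(X[:1], index=[1], columns=complete.columns)
        return TrajectoryClustering(subject_id, labels, 1, means, None)
    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(2, k_max + 1):
        model = AgglomerativeClustering(n_clusters=k, metric="euclidean",
                                        linkage="average")
        lab = model.fit_predict(X)
        score = silhouette_score(X, lab, metric="euclidean")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, lab
    # relabel clusters 1..k in order of first appearance (deterministic)
    remap: dict[int, int] = {}
    ordered = []
    for raw in best_labels:
        if raw not in remap:
            remap[raw] = len(remap) + 1
        ordered.append(remap[raw])
    labels = pd.Series(ordered, index=complete.index)
    means = complete.groupby(labels).mean()
    means.index.name = "cluster"
    return TrajectoryClustering(subject_id, labels, best_k, means,
                                float(best_score))


# ---------------------------------------------------------------------------
# Gene envelopes
# ---------------------------------------------------------------------------

@dataclass
class GeneEnvelope:
    """Per-timepoint min/mean/max of a gene's probes within one cluster."""

    cluster: int
    gene: str
    timepoints: tuple[str, ...]
    mean: tuple[float, ...]
    minimum: tuple[float, ...]
    maximum: tuple[float, ...]
    n_probes: int


def gene_envelopes(clustering: TrajectoryClustering, beta_subject,
                   annotation: ProbeAnnotation) -> list[GeneEnvelope]:
    """Envelopes for every (cluster, gene) represented by ≥ 2 probes.

    Genes carried by a single clustered probe are omitted, following the
    "≥ 2 dynamic CpGs" convention.
    """
    frame = _frame(beta_subject)
    pairs = annotation.table.dropna(subset=["gene"])
    out: list[GeneEnvelope] = []
    for cluster in sorted(clustering.labels.unique()):
        probes = set(clustering.labels.index[clustering.labels == cluster])
        sub = pairs[pairs["probe_id"].isin(probes)]
        for gene, grp in sub.groupby("gene", sort=True):
            gene_probe_ids = sorted(set(grp["probe_id"]) & set(frame.index))
            if len(gene_probe_ids) < 2:
                continue
            vals = frame.loc[gene_probe_ids]
            out.append(GeneEnvelope(
                cluster=int(cluster), gene=str(gene),
                timepoints=tuple(frame.columns),
                mean=tuple(vals.mean(axis=0)),
                minimum=tuple(vals.min(axis=0)),
                maximum=tuple(vals.max(axis=0)),
                n_probes=len(gene_probe_ids),
            ))
    return out
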