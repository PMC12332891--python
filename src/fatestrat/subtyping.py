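"""Consensus clustering of samples over fate genes and maturity subtyping.

Consensus clustering follows the classic resampling recipe: repeatedly
subsample samples and features, cut an agglomerative hierarchical
clustering (1 - Pearson correlation distance, average linkage by
default) at each k, and record how often each sample pair co-clusters
among the resamples where both were drawn.  The number of clusters is
chosen by the relative delta-area elbow of the consensus-value CDF.  A
PCA-derived score summarises fate-gene expression per sample, and at
k = 4 the clusters receive maturity labels I-IV anchored on the marker
genes SLIT3, ITGAX, PKIB and MCAM via an optimal one-to-one assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "SubtypeLabeling",
    "consensus_cluster",
    "select_k",
    "pca_score",
    "assign_subtypes",
    "SUBTYPE_MARKERS",
]

# maturity order I (high) .. IV (low) with its anchor marker
SUBTYPE_MARKERS: dict[str, str] = {
    "I": "SLIT3",
    "II": "ITGAX",
    "III": "PKIB",
    "IV": "MCAM",
}


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, pd.DataFrame]  # per k: samples x samples in [0, 1]
    assignments: dict[int, pd.Series]  # per k: cluster ids 1..k
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int | None = None


def _pairwise_distance(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(X, metric="correlation")
        if np.isnan(d).any():
            warnings.warn(
                "zero-variance samples: undefined correlation distances set to 0",
                stacklevel=3,
            )
            d = np.nan_to_num(d, nan=0.0)
        return np.clip(d, 0.0, None)
    return pdist(X, metric=metric)


def consensus_cluster(
    expr: ExpressionMatrix,
    k_range: range | list[int] = range(2, 10),
    reps: int = 100,
    p_sample: float = 0.8,
    p_feature: float = 0.8,
    linkage_method: str = "average",
    distance: str = "pearson",
    seed: int = 0,
) -> ConsensusResult:
    """Resampled hierarchical consensus clustering over the fate genes.

    Returns per-k consensus matrices, final assignments (hierarchical cut
    of 1 - consensus), CDF areas and relative delta-areas.
    """
    ks = sorted(k_range)
    n = expr.n_samples
    if n < max(ks) + 1:
        raise ValueError("need at least k_max + 1 samples")
    if expr.n_genes < 2:
        raise ValueError("need at least 2 fate genes")
    rng = np.random.default_rng(seed)
    X = expr.values.to_numpy().T  # samples x genes
    n_sub = max(2, int(np.ceil(p_sample * n)))
    f_sub = max(2, int(np.ceil(p_feature * X.shape[1])))

    co_sampled = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        s_idx = rng.choice(n, size=n_sub, replace=False)
        f_idx = rng.choice(X.shape[1], size=f_sub, replace=False)
        sub = X[np.ix_(s_idx, f_idx)]
        Z = linkage(_pairwise_distance(sub, distance), method=linkage_method)
        co_sampled[np.ix_(s_idx, s_idx)] += 1
        for k in ks:
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(s_idx, s_idx)] += same
    if (co_sampled == 0).any():
        raise ValueError(
            "some sample pair was never co-sampled; increase reps or p_sample"
        )

    samples = expr.samples
    consensus: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    cdf_area: dict[int, float] = {}
    for k in ks:
        M = co_cluster[k] / co_sampled
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)
        Z = linkage(squareform(1.0 - M, checks=False), method=linkage_method)
        labels = fcluster(Z, t=k, criterion="maxclust")
        assignments[k] = pd.Series(labels, index=samples, name=f"k{k}")
        cdf_area[k] = _cdf_area(M)

    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0
    return ConsensusResult(
        k_range=ks,
        consensus=consensus,
        assignments=assignments,
        cdf_area=cdf_area,
        delta_area=delta_area,
    )


def _cdf_area(M: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus values."""
    vals = np.sort(M[np.triu_indices_from(M, k=1)])
    if len(vals) == 0:
        return 0.0
    xs, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / len(vals)
    if len(xs) == 1:
        return float(xs[0] <= 1.0) * 0.0
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def select_k(result: ConsensusResult, threshold: float = 0.05) -> int:
    """Relative delta-area elbow: the largest k whose gain exceeds ``threshold``.

    The first k in the range is the baseline (always eligible); degenerate
    flat CDFs fall back to the smallest k with a warning.
    """
    ks = result.k_range
    if len(ks) < 3:
        raise ValueError("need at least 3 values of k")
    if all(result.cdf_area[k] <= 0 for k in ks):
        warnings.warn("degenerate consensus CDFs; returning k_min", stacklevel=2)
        result.chosen_k = ks[0]
        return ks[0]
    chosen = ks[0]
    for k in ks[1:]:
        if result.delta_area[k] > threshold:
            chosen = k
    result.chosen_k = chosen
    return chosen


def pca_score(expr: ExpressionMatrix) -> pd.Series:
    """Per-sample PC1 + PC2 coordinate over standardised fate genes.

    Each component's sign is anchored so it correlates non-negatively
    with mean fate-gene expression; the summed score is flipped as a
    final guard if needed.  Zero-variance genes are dropped with a
    warning.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = expr.values.to_numpy().T  # samples x genes
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance gene(s)", stacklevel=2
        )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with variance")
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    mean_expr = expr.values.to_numpy().mean(axis=0)  # per sample

    Xc = Xz - Xz.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :2] * S[:2]
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((len(coords), 1))])
    for j in range(2):
        if np.std(coords[:, j]) > 0 and np.corrcoef(coords[:, j], mean_expr)[0, 1] < 0:
            coords[:, j] = -coords[:, j]
    score = coords[:, 0] + coords[:, 1]
    if np.std(score) > 0 and np.corrcoef(score, mean_expr)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=expr.samples, name="pca_score")


@dataclass
class SubtypeLabeling:
    cluster_to_subtype: dict[int, str]
    evidence: pd.DataFrame  # clusters x markers, cluster-mean expression
    sample_subtype: pd.Series = field(default=None)


def assign_subtypes(
    result: ConsensusResult,
    expr: ExpressionMatrix,
    markers: dict[str, str] | None = None,
    k: int = 4,
) -> SubtypeLabeling:
    """Label the k = 4 consensus clusters I-IV by their anchor markers.

    The labelling maximises the total cluster-mean marker expression over
    one-to-one assignments (Hungarian algorithm), so exact ties resolve
    deterministically by assignment optimality rather than biology.
    """
    markers = dict(markers or SUBTYPE_MARKERS)
    if k != 4 or 4 not in result.assignments:
        raise ValueError("maturity labelling is defined for exactly 4 clusters")
    missing = [g for g in markers.values() if g not in expr.values.index]
    if missing:
        raise ValueError(f"marker gene(s) missing from matrix: {missing}")
    labels = result.assignments[4].loc[expr.samples]
    clusters = sorted(labels.unique())
    if len(clusters) != 4:
        raise ValueError("consensus assignment does not have 4 occupied clusters")
    evidence = pd.DataFrame(
        {
            sub: [
                float(expr.values.loc[gene, labels == cl].mean()) for cl in clusters
            ]
            for sub, gene in markers.items()
        },
        index=clusters,
    )
    row, col = linear_sum_assignment(-evidence.to_numpy())
    subs = list(evidence.columns)
    mapping = {clusters[r]: subs[c] for r, c in zip(row, col)}
    return SubtypeLabeling(
        cluster_to_subtype=mapping,
        evidence=evidence,
        sample_subtype=labels.map(mapping).rename("subtype"),
    )
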