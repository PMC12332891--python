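"""Spot/cell expression processing: normalisation, clustering, markers, MIA.

The stage mirrors a standard droplet/spot workflow: library-size
normalisation to 10k counts with log1p, vst-style highly variable gene
selection, PCA -> kNN graph -> Leiden community detection, one-vs-rest
Wilcoxon marker tests with Benjamini-Hochberg control, marker-panel spot
typing, and the hypergeometric multimodal intersection analysis (MIA)
used to compare marker sets across modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix

__all__ = [
    "qc_filter",
    "normalize_select_hvg",
    "reduce_cluster",
    "find_markers",
    "annotate_types",
    "SpotAnnotation",
    "mia_overlap",
]


def qc_filter(
    counts: ExpressionMatrix,
    max_transcripts: float = 100_000,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "MT-",
    min_cells_per_gene: int = 2,
) -> ExpressionMatrix:
    """Spot and gene quality filters applied before normalisation.

    Keeps spots with at most ``max_transcripts`` total counts and at most
    ``max_mito_frac`` mitochondrial fraction, and genes detected in more
    than ``min_cells_per_gene`` spots.  Thresholds are configurable; the
    transcript ceiling default is deliberately permissive.
    """
    values = counts.values
    totals = values.sum(axis=0)
    mito = values.index.str.startswith(mito_prefix)
    mito_frac = values.loc[mito].sum(axis=0) / totals.replace(0, np.nan)
    keep_spots = (totals <= max_transcripts) & (mito_frac.fillna(0.0) <= max_mito_frac)
    values = values.loc[:, keep_spots]
    keep_genes = (values > 0).sum(axis=1) > min_cells_per_gene
    meta = counts.sample_meta
    if meta is not None:
        meta = meta.loc[values.columns]
    return ExpressionMatrix(values.loc[keep_genes], layer="raw", sample_meta=meta)


def normalize_select_hvg(
    counts: ExpressionMatrix, n_hvg: int = 2000, target_sum: float = 1e4
) -> tuple[ExpressionMatrix, list[str]]:
    """Library-size normalisation (to ``target_sum``) + log1p, then HVGs.

    Highly variable genes are the top ``n_hvg`` by standardised dispersion:
    the residual of log-variance regressed on log-mean via a running-median
    trend, the usual vst-flavoured mean-variance detrending.
    """
    if counts.layer != "raw":
        raise ValueError("normalize_select_hvg expects a raw counts layer")
    values = counts.values.astype(float)
    totals = values.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} spot(s) with zero total counts",
            stacklevel=2,
        )
        values = values.loc[:, ~empty]
        totals = totals[~empty]
    norm = np.log1p(values / totals * target_sum)

    mean = norm.mean(axis=1).to_numpy()
    var = (
        norm.var(axis=1, ddof=1).to_numpy()
        if norm.shape[1] > 1
        else np.zeros(norm.shape[0])
    )
    # standardised dispersion: residual log-variance around a global
    # quadratic mean-variance trend (vst-style detrending)
    log_mean = np.log1p(mean)
    log_var = np.log1p(var)
    if len(log_mean) >= 5 and np.ptp(log_mean) > 0:
        coeffs = np.polyfit(log_mean, log_var, deg=2)
        trend = np.polyval(coeffs, log_mean)
    else:
        trend = np.full_like(log_var, log_var.mean())
    dispersion = pd.Series(log_var - trend, index=norm.index)
    hvg = dispersion.sort_values(ascending=False).head(n_hvg).index.tolist()

    meta = counts.sample_meta
    if meta is not None:
        meta = meta.loc[norm.columns]
    return ExpressionMatrix(norm, layer="normalised", sample_meta=meta), hvg


def reduce_cluster(
    norm: ExpressionMatrix,
    hvg: list[str] | None = None,
    n_pcs: int = 20,
    knn: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """PCA -> kNN graph -> Leiden modularity communities.

    Returns contiguous integer labels (0..k-1) indexed by spot, relabelled
    by decreasing community size for determinism.
    """
    import igraph
    import leidenalg

    if norm.layer != "normalised":
        raise ValueError("reduce_cluster expects a normalised layer")
    if norm.n_samples < knn + 1:
        raise ValueError(f"need more than knn+1={knn + 1} spots")
    X = norm.values if hvg is None else norm.values.loc[[g for g in hvg if g in norm.values.index]]
    mat = X.to_numpy().T  # spots x genes
    mat = mat - mat.mean(axis=0)
    n_comp = min(n_pcs, min(mat.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(mat)

    nn = NearestNeighbors(n_neighbors=knn + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=len(pcs), edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # contiguous ids ordered by size (ties by first occurrence)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[v] for v in labels])
    return pd.Series(labels, index=norm.samples, name="cluster")


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when both groups <= 8 and tie-free,
    normal approximation with tie correction otherwise."""
    method = "exact" if max(len(x), len(y)) <= 8 and len(np.unique(np.r_[x, y])) == len(x) + len(y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def find_markers(
    norm: ExpressionMatrix,
    labels: pd.Series,
    min_lfc: float = 0.5,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table with BH FDR per cluster.

    log2FC is computed on the de-logged normalised scale with a +1
    stabiliser: log2(mean(expm1(in)) + 1) - log2(mean(expm1(out)) + 1).
    Rows are filtered by |log2FC| > min_lfc and FDR < max_fdr; pass
    ``min_lfc=0, max_fdr=1`` to keep the full table.
    """
    if norm.layer != "normalised":
        raise ValueError("find_markers expects a normalised layer")
    labels = labels.loc[norm.samples]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    X = norm.values.to_numpy()
    rows = []
    for cl in clusters:
        in_mask = (labels == cl).to_numpy()
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {cl} has <3 spots; skipped", stacklevel=2)
            continue
        xin = X[:, in_mask]
        xout = X[:, ~in_mask]
        mean_in = np.expm1(xin).mean(axis=1)
        mean_out = np.expm1(xout).mean(axis=1)
        lfc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        pvals = np.array(
            [
                1.0 if np.ptp(X[g]) == 0 else _wilcoxon_p(xin[g], xout[g])
                for g in range(X.shape[0])
            ]
        )
        fdr = stats.false_discovery_control(pvals, method="bh")
        for g, gene in enumerate(norm.genes):
            rows.append((gene, cl, lfc[g], pvals[g], fdr[g]))
    table = pd.DataFrame(rows, columns=["gene", "cluster", "log2fc", "pvalue", "fdr"])
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    keep = (table["log2fc"].abs() > min_lfc) & (table["fdr"] < max_fdr)
    return table[keep].reset_index(drop=True)


@dataclass
class SpotAnnotation:
    """Cluster-level spot typing plus the per-spot expansion."""

    cluster_type: dict[int, str]
    spot_type: pd.Series
    scores: pd.DataFrame  # clusters x types, mean panel log2FC evidence


def annotate_types(
    markers: pd.DataFrame,
    panels: dict[str, list[str]],
    labels: pd.Series,
) -> SpotAnnotation:
    """Assign each cluster the panel with the highest mean marker log2FC.

    A panel's score in a cluster is the mean log2FC of its genes present
    in that cluster's marker rows (absent genes contribute 0).  Clusters
    with a non-positive best score, or an exact tie between panels, stay
    "unassigned" — ties are never broken arbitrarily.
    """
    if not panels or any(len(v) == 0 for v in panels.values()):
        raise ValueError("panels must be nonempty")
    flat = [g for p in panels.values() for g in p]
    if len(set(flat)) != len(flat):
        raise ValueError("panels must be disjoint")
    clusters = sorted(labels.unique())
    scores = pd.DataFrame(0.0, index=clusters, columns=list(panels))
    for cl in clusters:
        sub = markers[markers["cluster"] == cl].set_index("gene")["log2fc"]
        for t, panel in panels.items():
            vals = [float(sub.get(g, 0.0)) for g in panel]
            scores.loc[cl, t] = float(np.mean(vals))
    cluster_type: dict[int, str] = {}
    for cl in clusters:
        row = scores.loc[cl]
        best = row.max()
        if best <= 0 or (row == best).sum() > 1:
            cluster_type[cl] = "unassigned"
        else:
            cluster_type[cl] = str(row.idxmax())
    spot_type = labels.map(cluster_type).rename("spot_type")
    return SpotAnnotation(cluster_type=cluster_type, spot_type=spot_type, scores=scores)


def mia_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> dict[str, float]:
    """Hypergeometric intersection test between two gene sets.

    Returns the overlap size, the upper-tail enrichment p P(X >= k), the
    lower-tail depletion p P(X <= k), and -log10 of the enrichment p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(a), len(b)
    k = len(a & b)
    dist = stats.hypergeom(n_u, n_a, n_b)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    return {
        "overlap": k,
        "p_enrichment": min(p_enrich, 1.0),
        "p_depletion": min(p_deplete, 1.0),
        "neg_log10_p": float(-np.log10(max(p_enrich, np.finfo(float).tiny))),
    }
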