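"""Rank-based gene-set scoring and co-expression networks.

ssGSEA follows the weighted-ECDF-difference construction: per sample the
genes are ranked by expression and the enrichment score is the summed
difference between the weighted in-set and unweighted out-set empirical
CDFs, with rank weights raised to ``alpha``.  Cohort-level GSEA uses the
weighted Kolmogorov-Smirnov running sum on a pre-ranked list with a
gene-permutation null.  Correlation networks are all-pairs Pearson with
t-based p-values and BH control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_gmt",
    "ssgsea_score",
    "gsea_rank_test",
    "correlation_network",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list}; descriptions dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                continue
            if name in sets:
                raise ValueError(f"duplicate set name {name!r}")
            sets[name] = genes
    return sets


def _ssgsea_es(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Single-sample ES by direct running sum.

    ``expr`` is one sample's expression over all genes; ``in_set`` a
    boolean membership mask.  Genes are ordered by decreasing expression;
    the rank weight of the gene at position j (0-based) is (N - j)^alpha.
    Both the in-set and out-set ECDFs carry the rank weights and the
    summed difference is divided by N — this symmetrised, length-
    normalised variant keeps the score of a random set centred at zero,
    unlike the hit-weighted-only running sum.
    """
    order = np.argsort(-expr, kind="stable")
    hits = in_set[order]
    n = len(expr)
    weights = (n - np.arange(n)).astype(float) ** alpha
    w_hit = np.where(hits, weights, 0.0)
    w_miss = np.where(~hits, weights, 0.0)
    cdf_hit = np.cumsum(w_hit) / w_hit.sum()
    cdf_miss = np.cumsum(w_miss) / w_miss.sum()
    return float(np.sum(cdf_hit - cdf_miss) / n)


def ssgsea_score(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalise: bool = False,
) -> pd.DataFrame:
    """Per-(set, sample) ssGSEA enrichment scores.

    ``expr`` is genes x samples.  Sets with fewer than 2 present genes are
    skipped with a warning; a set covering every gene has no out-set ECDF
    and is likewise skipped.  With ``normalise=True`` scores are min-max
    scaled across the whole result (the usual cross-sample normalisation).
    """
    genes = expr.index
    X = expr.to_numpy()
    rows = {}
    for name, members in sets.items():
        mask = np.asarray(genes.isin(members))
        if mask.sum() < 2:
            warnings.warn(f"set {name!r} overlaps <2 genes; skipped", stacklevel=2)
            continue
        if mask.all():
            warnings.warn(f"set {name!r} covers all genes; skipped", stacklevel=2)
            continue
        rows[name] = [
            _ssgsea_es(X[:, j], mask, alpha) for j in range(X.shape[1])
        ]
    if not rows:
        raise ValueError("no scorable gene set")
    result = pd.DataFrame(rows, index=expr.columns).T
    if normalise:
        lo, hi = result.to_numpy().min(), result.to_numpy().max()
        if hi > lo:
            result = (result - lo) / (hi - lo)
    return result


def _gsea_es(weights_ranked: np.ndarray, hits: np.ndarray) -> float:
    """Weighted KS running-sum ES (weight exponent 1) for one set."""
    w = np.abs(weights_ranked)
    w_hit = np.where(hits, w, 0.0)
    denom = w_hit.sum()
    n_miss = len(hits) - int(hits.sum())
    if denom == 0 or n_miss == 0:
        return 0.0
    running = np.cumsum(w_hit / denom - (~hits) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_rank_test(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    nperm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-permutation null.

    ``ranked`` maps gene -> signed ranking weight (e.g. log2FC), sorted
    by decreasing weight (it is re-sorted here defensively).  NES divides
    the ES by the mean |null ES| of the same sign; the permutation p uses
    the same-sign null with the add-one rule.
    """
    if nperm < 10:
        raise ValueError("nperm must be >= 10")
    if ranked.index.duplicated().any():
        raise ValueError("ranked list has duplicate genes")
    ranked = ranked.sort_values(ascending=False)
    genes = ranked.index.to_numpy()
    weights = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(genes)

    rows = []
    for name, members in sets.items():
        hits = np.isin(genes, list(members))
        k = int(hits.sum())
        if k < 1 or k >= n:
            warnings.warn(f"set {name!r} not scorable; skipped", stacklevel=2)
            continue
        es = _gsea_es(weights, hits)
        null = np.empty(nperm)
        for b in range(nperm):
            perm_hits = np.zeros(n, dtype=bool)
            perm_hits[rng.choice(n, size=k, replace=False)] = True
            null[b] = _gsea_es(weights, perm_hits)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / np.mean(np.abs(same))
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
        rows.append((name, es, nes, p))
    result = pd.DataFrame(rows, columns=["set", "es", "nes", "pvalue"]).set_index("set")
    result["fdr"] = stats.false_discovery_control(result["pvalue"], method="bh")
    return result


def correlation_network(
    matrix: pd.DataFrame, r_min: float = 0.0, p_max: float = 1.0
) -> pd.DataFrame:
    """All-pairs Pearson edges (entities x samples input).

    Zero-variance entities are dropped with a warning.  Each unordered
    pair appears once; p-values are two-sided t-based and BH-adjusted
    across all pairs before filtering by |R| >= r_min and adjusted
    p <= p_max.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = matrix.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"dropping {int((sd == 0).sum())} zero-variance entit(ies)", stacklevel=2
        )
        matrix = matrix.loc[sd > 0]
    names = matrix.index.to_list()
    X = matrix.to_numpy()
    n = X.shape[1]
    R = np.corrcoef(X)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(np.clip(R[i, j], -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r**2))
                p = float(2 * stats.t.sf(abs(t), n - 2))
            rows.append((names[i], names[j], r, p))
    edges = pd.DataFrame(rows, columns=["entity_a", "entity_b", "r", "pvalue"])
    if len(edges):
        edges["fdr"] = stats.false_discovery_control(edges["pvalue"], method="bh")
        edges = edges[(edges["r"].abs() >= r_min) & (edges["fdr"] <= p_max)]
    return edges.reset_index(drop=True)
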