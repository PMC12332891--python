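"""Subtype-to-cell-line matching and drug-response transfer.

Cell lines are matched to cohort consensus clusters by Pearson
correlation of z-standardised fate-gene profiles against cluster
centroids, hard-assigned to the argmax cluster.  Per-drug differences
across the assigned groups are tested with Kruskal-Wallis (BH across
drugs), and significant drugs are ranked per subtype by their
direction-aware median sensitivity advantage.  Because public response
measures disagree on whether larger values mean more or less sensitive,
every response table must carry an explicit direction flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "match_cell_lines",
    "drug_subtype_test",
    "rank_drugs",
    "assignment_cv",
]

_DIRECTIONS = ("higher_is_sensitive", "lower_is_sensitive")


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0).replace(0, 1.0)
    return values.sub(mean, axis=0).div(sd, axis=0)


def _centroids(
    cohort: ExpressionMatrix, labels: pd.Series, genes: list[str]
) -> pd.DataFrame:
    z = _zscore_rows(cohort.values.loc[genes])
    return pd.DataFrame(
        {cl: z.loc[:, labels == cl].mean(axis=1) for cl in sorted(labels.unique())}
    )


def match_cell_lines(
    cohort: ExpressionMatrix,
    labels: pd.Series,
    lines: ExpressionMatrix,
    fate_genes: list[str],
    min_pcc: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Similarity matrix (lines x clusters) and argmax assignment.

    Genes are z-standardised within each cohort separately; a line whose
    best correlation falls below ``min_pcc`` (or whose profile is
    constant) is left unmatched (NaN).
    """
    shared = [
        g for g in fate_genes if g in cohort.values.index and g in lines.values.index
    ]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared fate genes between cohorts")
    labels = labels.loc[cohort.samples]
    cents = _centroids(cohort, labels, shared)
    line_z = _zscore_rows(lines.values.loc[shared])

    raw = lines.values.loc[shared]
    sim = pd.DataFrame(index=lines.samples, columns=cents.columns, dtype=float)
    for line in lines.samples:
        x = line_z[line].to_numpy()
        if np.std(x) == 0 or float(raw[line].std()) == 0:
            warnings.warn(f"constant profile for line {line!r}; unmatched", stacklevel=2)
            sim.loc[line] = np.nan
            continue
        for cl in cents.columns:
            sim.loc[line, cl] = float(np.corrcoef(x, cents[cl].to_numpy())[0, 1])
    best = sim.idxmax(axis=1)
    best_val = sim.max(axis=1)
    assignment = best.where(best_val >= min_pcc)
    assignment.name = "cluster"
    return sim, assignment


def drug_subtype_test(
    response: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """Per-drug Kruskal-Wallis H across assigned clusters, BH over drugs.

    ``response`` has columns cell_line, drug, response.  Drugs with
    values in fewer than 2 clusters (each needing >= 2 lines) are skipped
    with a warning.
    """
    merged = response.merge(
        assignment.rename("cluster"), left_on="cell_line", right_index=True
    ).dropna(subset=["cluster"])
    rows = []
    for drug, sub in merged.groupby("drug", sort=True):
        groups = [
            g["response"].to_numpy()
            for _, g in sub.groupby("cluster")
            if len(g) >= 2
        ]
        if len(groups) < 2:
            warnings.warn(f"drug {drug!r} observed in <2 clusters; skipped", stacklevel=2)
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append((drug, float(h), float(p)))
    result = pd.DataFrame(rows, columns=["drug", "H", "pvalue"]).set_index("drug")
    if len(result):
        result["fdr"] = stats.false_discovery_control(result["pvalue"], method="bh")
    return result


def rank_drugs(
    response: pd.DataFrame,
    assignment: pd.Series,
    significant: list[str],
    direction: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-subtype ranking of significant drugs by sensitivity advantage.

    Advantage = (median response in the subtype - median elsewhere),
    sign-corrected by the direction flag so larger always means more
    sensitive.  ``direction`` defaults to ``response.attrs['direction']``
    and must be declared one way or the other.
    """
    direction = direction or response.attrs.get("direction")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction flag required, one of {_DIRECTIONS}")
    sign = 1.0 if direction == "higher_is_sensitive" else -1.0
    merged = response.merge(
        assignment.rename("cluster"), left_on="cell_line", right_index=True
    ).dropna(subset=["cluster"])
    merged = merged[merged["drug"].isin(significant)]
    out: dict[str, pd.DataFrame] = {}
    for cl in sorted(assignment.dropna().unique()):
        rows = []
        for drug, sub in merged.groupby("drug"):
            inside = sub.loc[sub["cluster"] == cl, "response"]
            outside = sub.loc[sub["cluster"] != cl, "response"]
            if len(inside) == 0 or len(outside) == 0:
                continue
            adv = sign * float(inside.median() - outside.median())
            rows.append((drug, adv))
        table = pd.DataFrame(rows, columns=["drug", "advantage"])
        out[cl] = table.sort_values(
            "advantage", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return out


def assignment_cv(
    cohort: ExpressionMatrix,
    labels: pd.Series,
    lines: ExpressionMatrix,
    fate_genes: list[str],
    folds: int = 10,
    seed: int = 0,
    min_pcc: float = 0.0,
) -> pd.Series:
    """Centroid-stability cross-validation of the line assignment.

    Cohort samples are split into folds; centroids are recomputed with
    each fold held out and lines re-assigned.  Returns the per-line
    fraction of folds agreeing with the full-data assignment.
    """
    labels = labels.loc[cohort.samples]
    if labels.value_counts().min() < folds:
        raise ValueError("folds exceeds the smallest cluster size")
    _, full = match_cell_lines(cohort, labels, lines, fate_genes, min_pcc)
    rng = np.random.default_rng(seed)
    fold_of = pd.Series(
        rng.permuted(np.arange(len(labels)) % folds), index=labels.index
    )
    agree = pd.Series(0.0, index=lines.samples)
    for f in range(folds):
        keep = fold_of != f
        sub = ExpressionMatrix(
            cohort.values.loc[:, keep], layer=cohort.layer
        )
        _, assignment = match_cell_lines(sub, labels[keep], lines, fate_genes, min_pcc)
        agree += (assignment == full).astype(float)
    return (agree / folds).rename("agreement")
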