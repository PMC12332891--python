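"""Branching pseudotime for malignant spots and the fate-gene cascade.

The trajectory here is a deliberately simple rooted branching order:
PCA to two components on the ordering genes, k-means centroids, a
minimum spanning tree over the centroids, and projection of every spot
onto its nearest tree edge.  Pseudotime is geodesic distance from the
root along the tree; states are the tree segments between nodes of
degree != 2.  This captures exactly what the downstream fate-gene
selection needs — an ordering plus branch labels — without attempting a
full probabilistic-graph embedding.

Differential tests are Gaussian-working-likelihood LRTs of natural cubic
spline regressions on pseudotime, with a spline-by-branch interaction
test at a bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix

__all__ = [
    "TrajectoryResult",
    "FateGeneCascade",
    "fit_trajectory",
    "natural_spline_basis",
    "pseudotime_de",
    "branch_de",
    "select_fate_genes",
]

DEFAULT_MATURITY_PANEL = ["SLIT3", "ITGAX"]


@dataclass
class TrajectoryResult:
    pseudotime: pd.Series  # >= 0, root spots at the minimum 0
    state: pd.Series  # segment label per spot
    branches: dict[int, pd.Series]  # branch node -> per-spot arm label (0 = root side)
    tree: nx.Graph  # centroid tree; node attr "pos" = 2-D embedding
    root: int
    embedding: pd.DataFrame  # spots x (pc1, pc2)


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Return (distance to segment ab, unclamped projection parameter t)."""
    ab = b - a
    denom = float(ab @ ab)
    t_raw = 0.0 if denom == 0 else float((p - a) @ ab / denom)
    t = np.clip(t_raw, 0.0, 1.0)
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t_raw


def fit_trajectory(
    norm: ExpressionMatrix,
    ordering_genes: list[str],
    n_centroids: int = 10,
    root: int | list[str] | None = None,
    seed: int = 0,
) -> TrajectoryResult:
    """Centroid-MST trajectory over the ordering genes.

    ``root`` may be an explicit tree-node id, a "maturity" gene panel
    (the leaf whose member spots have the lowest mean panel expression
    becomes the root), or None to use the default SLIT3/ITGAX panel when
    present (falling back to the leaf with the lowest mean first
    principal component, a deterministic anchor).
    """
    if n_centroids < 3:
        raise ValueError("n_centroids must be >= 3 (no branch possible otherwise)")
    genes = [g for g in ordering_genes if g in norm.values.index]
    if not genes:
        raise ValueError("no ordering genes present in the matrix")
    if norm.n_samples < n_centroids:
        raise ValueError("need at least n_centroids spots")
    X = norm.values.loc[genes].to_numpy().T  # spots x genes
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    emb = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(X)

    # deterministic, spot-order-invariant init: centroid seeds at evenly
    # spaced quantiles of the lexicographic (pc1, pc2) ordering
    order = np.lexsort((emb[:, 1], emb[:, 0]))
    picks = order[np.linspace(0, len(order) - 1, n_centroids).round().astype(int)]
    km = KMeans(
        n_clusters=n_centroids, init=emb[picks], n_init=1, random_state=seed
    ).fit(emb)
    centroids = km.cluster_centers_

    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    mst = minimum_spanning_tree(dist).toarray()
    tree = nx.Graph()
    for i in range(n_centroids):
        tree.add_node(i, pos=tuple(centroids[i]))
    for i, j in zip(*np.nonzero(mst)):
        tree.add_edge(int(i), int(j), weight=float(dist[i, j]))

    # project each spot to its nearest tree edge
    edges = list(tree.edges())
    edge_proj = np.empty(len(emb), dtype=int)
    t_param = np.empty(len(emb))
    for s, p in enumerate(emb):
        best = (np.inf, 0, 0.0)
        for e_idx, (u, v) in enumerate(edges):
            d, t_raw = _project_to_segment(p, centroids[u], centroids[v])
            if d < best[0]:
                best = (d, e_idx, t_raw)
        edge_proj[s] = best[1]
        t_param[s] = best[2]

    root_node = _resolve_root(norm, tree, km.labels_, root, emb)

    node_dist = nx.single_source_dijkstra_path_length(tree, root_node, weight="weight")
    degree = dict(tree.degree())
    pt = np.empty(len(emb))
    for s in range(len(emb)):
        u, v = edges[edge_proj[s]]
        t = t_param[s]
        # orient the edge away from the root
        if node_dist[u] > node_dist[v]:
            u, v = v, u
            t = 1.0 - t
        # spots beyond a leaf endpoint keep their graded ordering; spots
        # beyond an interior junction are clamped onto the tree
        lo = -np.inf if degree[u] == 1 else 0.0
        hi = np.inf if degree[v] == 1 else 1.0
        t = float(np.clip(t, lo, hi))
        pt[s] = node_dist[u] + t * tree[u][v]["weight"]
    pt -= pt.min()

    seg_of_edge = _segment_labels(tree)
    state = np.array([seg_of_edge[frozenset(edges[e])] for e in edge_proj])

    branches: dict[int, pd.Series] = {}
    for node in tree.nodes:
        if tree.degree(node) >= 3:
            arm = _branch_labels(tree, node, root_node, edges, edge_proj)
            branches[node] = pd.Series(arm, index=norm.samples, name=f"branch@{node}")

    return TrajectoryResult(
        pseudotime=pd.Series(pt, index=norm.samples, name="pseudotime"),
        state=pd.Series(state, index=norm.samples, name="state"),
        branches=branches,
        tree=tree,
        root=root_node,
        embedding=pd.DataFrame(emb, index=norm.samples, columns=["pc1", "pc2"]),
    )


def _resolve_root(norm, tree, spot_node, root, emb) -> int:
    leaves = sorted(n for n in tree.nodes if tree.degree(n) == 1)
    if isinstance(root, (int, np.integer)):
        if root not in tree.nodes:
            raise ValueError(f"root node {root} not in tree")
        return int(root)
    panel = root
    if panel is None:
        panel = [g for g in DEFAULT_MATURITY_PANEL if g in norm.values.index]
    else:
        panel = [g for g in panel if g in norm.values.index]
    if panel:
        panel_mean = norm.values.loc[panel].mean(axis=0).to_numpy()
        means = {
            leaf: float(panel_mean[spot_node == leaf].mean())
            if (spot_node == leaf).any()
            else np.inf
            for leaf in leaves
        }
        return min(leaves, key=lambda n: (means[n], n))
    pc1 = {
        leaf: float(emb[spot_node == leaf, 0].mean())
        if (spot_node == leaf).any()
        else np.inf
        for leaf in leaves
    }
    return min(leaves, key=lambda n: (pc1[n], n))


def _segment_labels(tree: nx.Graph) -> dict[frozenset, int]:
    """Label tree edges by the segment (maximal degree-2 chain) they lie on."""
    anchors = {n for n in tree.nodes if tree.degree(n) != 2}
    if not anchors:  # cycle-free chain degenerate case: whole tree one segment
        anchors = {min(tree.nodes)}
    seg_of_edge: dict[frozenset, int] = {}
    seg = 0
    visited = set()
    for a in sorted(anchors):
        for nb in sorted(tree.neighbors(a)):
            if frozenset((a, nb)) in visited:
                continue
            # walk the chain until the next anchor
            chain = [(a, nb)]
            prev, cur = a, nb
            while cur not in anchors:
                nxt = next(n for n in tree.neighbors(cur) if n != prev)
                chain.append((cur, nxt))
                prev, cur = cur, nxt
            for e in chain:
                visited.add(frozenset(e))
                seg_of_edge[frozenset(e)] = seg
            seg += 1
    return seg_of_edge


def _branch_labels(tree, node, root_node, edges, edge_proj) -> np.ndarray:
    work = tree.copy()
    work.remove_node(node)
    comps = sorted(nx.connected_components(work), key=min)
    comp_of: dict[int, int] = {}
    arm = 1
    for comp in comps:
        if root_node in comp:
            for n in comp:
                comp_of[n] = 0
        else:
            for n in comp:
                comp_of[n] = arm
            arm += 1
    labels = np.empty(len(edge_proj), dtype=int)
    for s, e in enumerate(edge_proj):
        u, v = edges[e]
        cu = comp_of.get(u, None)
        cv = comp_of.get(v, None)
        # edges incident to the branch node inherit the other endpoint's side
        labels[s] = cu if cv is None else cv if cu is None else max(cu, cv)
    return labels


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary knots at min/max of x, internal knots at quantiles — the
    standard truncated-power construction with linearity constraints
    beyond the boundaries.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    n_knots = df + 1
    probs = np.linspace(0, 1, n_knots)
    knots = np.unique(np.quantile(x, probs))
    if len(knots) < 2:
        raise ValueError("pseudotime is constant")
    if len(knots) < n_knots:  # heavy ties: fall back to polynomial basis
        return np.column_stack([x**k for k in range(1, df + 1)])
    xi = knots
    K = len(xi)

    def d(k: int) -> np.ndarray:
        num = np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def _lrt_gaussian(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray, df: int):
    """Vectorised Gaussian LRT per response row of Y.

    stat = n * log(RSS_reduced / RSS_full), chi-square reference with df.
    """
    n = Y.shape[1]

    def rss(X: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(X)
        resid = Y.T - Q @ (Q.T @ Y.T)
        return (resid**2).sum(axis=0)

    rss_full = rss(X_full)
    rss_red = rss(X_red)
    eps = np.finfo(float).tiny
    stat = n * np.log(np.maximum(rss_red, eps) / np.maximum(rss_full, eps))
    stat = np.clip(stat, 0.0, None)
    stat[rss_red <= eps] = 0.0  # constant gene: both models saturate
    p = stats.chi2.sf(stat, df)
    return stat, p


def pseudotime_de(
    expr: ExpressionMatrix, pseudotime: pd.Series, spline_df: int = 3
) -> pd.DataFrame:
    """Per-gene LRT of spline(pseudotime) vs intercept-only; BH q-values."""
    pt = pseudotime.loc[expr.samples].to_numpy(dtype=float)
    if np.ptp(pt) == 0:
        raise ValueError("pseudotime is constant")
    if expr.n_samples < 2 * spline_df + 2:
        raise ValueError("too few spots for the requested spline_df")
    basis = natural_spline_basis(pt, df=spline_df)
    ones = np.ones((len(pt), 1))
    X_full = np.hstack([ones, basis])
    Y = expr.values.to_numpy()
    stat, p = _lrt_gaussian(Y, X_full, ones, df=basis.shape[1])
    q = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {"stat": stat, "pvalue": p, "qvalue": q}, index=expr.genes
    )


def branch_de(
    expr: ExpressionMatrix, pseudotime: pd.Series, branch: pd.Series, spline_df: int = 3
) -> pd.DataFrame:
    """Spline-by-branch interaction LRT at one bifurcation.

    Spots labelled with the two arm values are compared; the reduced
    model is a shared spline of pseudotime, the full model adds a branch
    main effect and per-branch spline terms.  The reported ``sign`` is
    the difference of fitted terminal means (first arm minus second), a
    branch-preference direction per gene.
    """
    branch = branch.loc[expr.samples]
    arms = sorted(v for v in branch.dropna().unique() if v != 0)
    if len(arms) < 2:
        raise ValueError("need two branch arms")
    arms = arms[:2]
    mask = branch.isin(arms).to_numpy()
    pt = pseudotime.loc[expr.samples].to_numpy(dtype=float)[mask]
    grp = (branch[mask] == arms[1]).to_numpy().astype(float)
    if min((grp == 0).sum(), (grp == 1).sum()) < spline_df + 2:
        raise ValueError("each branch needs at least spline_df + 2 spots")
    Y = expr.values.to_numpy()[:, mask]

    basis = natural_spline_basis(pt, df=spline_df)
    ones = np.ones((mask.sum(), 1))
    X_red = np.hstack([ones, basis])
    X_full = np.hstack([ones, basis, grp[:, None], basis * grp[:, None]])
    stat, p = _lrt_gaussian(Y, X_full, X_red, df=basis.shape[1] + 1)
    q = stats.false_discovery_control(p, method="bh")

    # terminal fitted means at the pseudotime maximum of each arm
    beta, *_ = np.linalg.lstsq(X_full, Y.T, rcond=None)
    signs = np.empty(Y.shape[0])
    t_max = pt.max()
    b_t = natural_spline_basis(np.r_[pt, t_max], df=spline_df)[-1]
    x0 = np.r_[1.0, b_t, 0.0, np.zeros_like(b_t)]
    x1 = np.r_[1.0, b_t, 1.0, b_t]
    signs = (x0 - x1) @ beta  # arm[0] terminal mean minus arm[1]
    return pd.DataFrame(
        {"stat": stat, "pvalue": p, "qvalue": q, "sign": np.sign(signs)},
        index=expr.genes,
    )


@dataclass
class FateGeneCascade:
    """Intermediate and final gene sets of the fate-gene selection cascade."""

    trajectory_de: set[str]
    ordering: set[str]
    state_related: set[str] = field(init=False)
    km_significant: set[str] = field(default_factory=set)
    unicox_significant: set[str] = field(default_factory=set)
    final: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.state_related = self.trajectory_de & self.ordering
        self.final = self.state_related & self.km_significant & self.unicox_significant

    def sizes(self) -> dict[str, int]:
        return {
            "trajectory_de": len(self.trajectory_de),
            "ordering": len(self.ordering),
            "state_related": len(self.state_related),
            "km_significant": len(self.km_significant),
            "unicox_significant": len(self.unicox_significant),
            "final": len(self.final),
        }


def select_fate_genes(
    traj_q: pd.Series,
    ordering_genes: list[str],
    km_p: pd.Series,
    unicox_p: pd.Series,
    q_max: float = 0.05,
    p_km: float = 0.05,
    p_cox: float = 0.05,
) -> FateGeneCascade:
    """Deterministic set algebra of the fate-gene cascade.

    final = (trajectory-DE ∩ ordering genes) ∩ KM-significant ∩
    uniCox-significant.  An empty final set is a warning condition for
    the caller, not an error.
    """
    cascade = FateGeneCascade(
        trajectory_de={g for g, q in traj_q.items() if q < q_max},
        ordering=set(ordering_genes),
        km_significant={g for g, p in km_p.items() if p < p_km},
        unicox_significant={g for g, p in unicox_p.items() if p < p_cox},
    )
    return cascade
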