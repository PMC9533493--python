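"""Co-abundance networks, Markov clustering and redundancy-based reduction.

The candidate features for the breeding index are pruned in three steps:
(1) a co-abundance network over pre-corrected phenotypes or breeding values
(edges where |Pearson r| > 0.30) clustered with the Markov Clustering
algorithm, (2) an abundance floor (mean relative abundance of the numerator
part >= 0.01%), and (3) a redundancy analysis that drops candidates whose
marginal contribution to explaining the breeding-value variance of the full
feature set is not significant under a permutation F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .coda import CompositionTable


def precorrect_phenotypes(
    traits: pd.DataFrame, fixed_factor
) -> tuple[pd.DataFrame, pd.Series]:
    """Residuals from per-level means of a single categorical factor.

    Returns the residual table and the per-trait R-squared of the factor.
    Levels with a single animal contribute zero residuals (flagged).
    """
    codes = pd.Categorical(np.asarray(fixed_factor))
    if len(codes) != len(traits):
        raise ValueError("fixed_factor length must match the trait table")
    values = traits.to_numpy(float)
    idx = np.asarray(codes.codes)
    L = len(codes.categories)
    counts = np.bincount(idx, minlength=L).astype(float)
    if (counts == 1).any():
        warnings.warn("factor level with a single animal: residual forced to 0", stacklevel=2)
    sums = np.stack(
        [np.bincount(idx, weights=values[:, t], minlength=L) for t in range(values.shape[1])],
        axis=1,
    )
    level_means = sums / counts[:, None]
    resid = values - level_means[idx]
    total_ss = ((values - values.mean(axis=0)) ** 2).sum(axis=0)
    resid_ss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(total_ss > 0, 1.0 - resid_ss / total_ss, np.nan)
    return (
        pd.DataFrame(resid, index=traits.index, columns=traits.columns),
        pd.Series(r2, index=traits.columns, name="r_squared"),
    )


def variance_explained_multivariate(responses: pd.DataFrame, fixed_factor) -> float:
    """Proportion of total sum of squares explained by factor-level means.

    This is the constrained-inertia fraction of a one-way redundancy
    analysis with a single categorical constraint (equal to the one-way
    ANOVA R-squared for a single response column).
    """
    codes = pd.Categorical(np.asarray(fixed_factor))
    if len(codes.categories) < 2:
        raise ValueError("need at least 2 factor levels")
    values = np.asarray(responses, float)
    if values.ndim == 1:
        values = values[:, None]
    centered = values - values.mean(axis=0)
    total = float((centered**2).sum())
    if total <= 0:
        raise ValueError("responses have zero total variance")
    idx = np.asarray(codes.codes)
    L = len(codes.categories)
    counts = np.bincount(idx, minlength=L).astype(float)
    counts = np.where(counts == 0, 1.0, counts)
    sums = np.stack(
        [np.bincount(idx, weights=centered[:, t], minlength=L) for t in range(centered.shape[1])],
        axis=1,
    )
    means = sums / counts[:, None]
    between = float((counts[:, None] * means**2).sum())
    return between / total


@dataclass
class CoabundanceGraph:
    """Weighted undirected feature graph (signed Pearson r edge weights)."""

    graph: nx.Graph
    basis: str  # "phenotypic" or "genomic"
    threshold: float
    excluded: list[str]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def write_edge_tsv(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    values: pd.DataFrame, r_threshold: float = 0.30, basis: str = "phenotypic"
) -> CoabundanceGraph:
    """Edge (i, j) iff |Pearson r| strictly exceeds the threshold.

    Zero-variance feature columns are excluded with a warning; isolated
    features remain as nodes without edges.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 animals to correlate features")
    sd = values.std(ddof=1)
    excluded = list(values.columns[(sd == 0) | sd.isna()])
    if excluded:
        warnings.warn(f"excluding zero-variance features: {excluded}", stacklevel=2)
    kept = values.drop(columns=excluded)
    cols = list(kept.columns.astype(str))
    r = np.corrcoef(kept.to_numpy(float), rowvar=False)
    g = nx.Graph()
    g.add_nodes_from(cols)
    iu, ju = np.triu_indices(len(cols), k=1)
    for i, j in zip(iu, ju):
        if abs(r[i, j]) > r_threshold:
            g.add_edge(cols[i], cols[j], weight=float(r[i, j]))
    return CoabundanceGraph(graph=g, basis=basis, threshold=r_threshold, excluded=excluded)


@dataclass
class Clustering:
    """MCL partition; clusters below the granularity are left unclustered."""

    assignments: pd.Series  # node -> cluster id (<NA> for unclustered)
    min_cluster_size: int
    converged: bool
    n_iterations: int

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.assignments.items():
            if pd.isna(cid):
                continue
            out.setdefault(int(cid), []).append(node)
        return out

    def write_csv(self, path) -> None:
        self.assignments.rename("cluster").to_csv(path, index_label="node")


def mcl_cluster(
    graph: CoabundanceGraph | nx.Graph,
    inflation: float = 2.0,
    min_cluster_size: int = 2,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> Clustering:
    """Markov clustering by alternating expansion and inflation.

    The column-stochastic transition matrix is built from absolute edge
    weights with unit self-loops; expansion is matrix squaring, inflation an
    elementwise power followed by column renormalization. At convergence the
    rows with mass (attractors) define the clusters.
    """
    g = graph.graph if isinstance(graph, CoabundanceGraph) else graph
    nodes = list(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    a = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
    np.fill_diagonal(a, 1.0)
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        raise RuntimeError(f"MCL did not converge within {max_iter} iterations")
    # attractor interpretation: each nonzero row groups the columns it serves
    attractors = np.where(np.diag(m) > 1e-6)[0]
    clusters: list[set[int]] = []
    for a_i in attractors:
        members = set(np.where(m[a_i] > 1e-6)[0]) | {int(a_i)}
        clusters.append(members)
    # merge overlapping attractor systems transitively
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    assigned = pd.Series([pd.NA] * n, index=nodes, dtype="object")
    cid = 0
    for members in sorted(clusters, key=lambda c: (-len(c), min(c))):
        if len(members) >= min_cluster_size:
            for k in members:
                assigned.iloc[k] = cid
            cid += 1
    return Clustering(
        assignments=assigned,
        min_cluster_size=min_cluster_size,
        converged=converged,
        n_iterations=it,
    )


def abundance_filter(
    candidates: list[str], table: CompositionTable, min_mean_ra: float = 1e-4
) -> list[str]:
    """Keep features whose numerator mean relative abundance is >= the floor."""
    mean_ra = dict(zip(table.part_ids, table.mean_ra))
    missing = [c for c in candidates if c not in mean_ra]
    if missing:
        raise KeyError(f"features not in composition table: {missing}")
    return [c for c in candidates if mean_ra[c] >= min_mean_ra]


def rda_redundancy_select(
    response: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Drop candidates that are redundant for explaining a multivariate response.

    Redundancy analysis: multivariate least squares of the (column-centred)
    response matrix on the candidate matrix. Each candidate's marginal
    contribution is tested with a Freedman-Lane permutation F-test: residuals
    of the model *without* that candidate are permuted, added back to its
    fitted values, and the marginal F recomputed. Candidates with p > alpha
    are discarded.
    """
    if len(candidates.columns) >= len(response):
        raise ValueError("candidate count must be below the animal count")
    sd = candidates.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant candidates: {list(candidates.columns[sd == 0])}")
    rng = np.random.default_rng(seed)
    Y = np.asarray(response, float)
    Y = Y - Y.mean(axis=0)
    X = np.asarray(candidates, float)
    X = X - X.mean(axis=0)
    names = list(candidates.columns.astype(str))
    n, q = X.shape

    # collinearity guard: drop later duplicates via rank-revealing QR
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        warnings.warn("collinear candidates: dropping later dependent columns", stacklevel=2)
        keep: list[int] = []
        for j in range(q):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        X = X[:, keep]
        dropped = [names[j] for j in range(q) if j not in keep]
        names = [names[j] for j in keep]
        q = len(names)
    else:
        dropped = []

    qf, _ = np.linalg.qr(X)

    def rss_from(qmat: np.ndarray | None, Ym: np.ndarray) -> float:
        total = float((Ym**2).sum())
        if qmat is None or qmat.shape[1] == 0:
            return total
        return total - float(((qmat.T @ Ym) ** 2).sum())

    rss_full = rss_from(qf, Y)
    df_res = n - 1 - q
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom left for the F-test")
    total_y = float((Y**2).sum())

    def f_stat(rss_red: float, rss_f: float) -> float:
        # exact fit (rss ~ 0, e.g. response spanned by the candidates):
        # F is +inf when removing the candidate loses fit, else 0
        if rss_f <= 1e-12 * max(total_y, 1.0):
            return float("inf") if rss_red > 1e-12 * max(total_y, 1.0) else 0.0
        return (rss_red - rss_f) / (rss_f / df_res)

    pvals = {}
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        qo, _ = np.linalg.qr(others) if others.shape[1] else (None, None)
        fitted_o = qo @ (qo.T @ Y) if qo is not None else np.zeros_like(Y)
        resid_o = Y - fitted_o
        rss_red = float((resid_o**2).sum())
        f_obs = f_stat(rss_red, rss_full)
        count = 1
        for _ in range(n_perm):
            Yp = fitted_o + resid_o[rng.permutation(n)]
            f_perm = f_stat(rss_from(qo, Yp), rss_from(qf, Yp))
            if f_perm >= f_obs:
                count += 1
        pvals[name] = count / (n_perm + 1)
    for name in dropped:
        pvals[name] = 1.0
    pser = pd.Series(pvals, name="p_value")
    retained = [name for name in names if pvals[name] <= alpha]
    return retained, pser
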