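"""Dimensionality reduction, graph clustering and per-cluster marker tests.

The clustering route is the standard single-cell recipe: PCA on a
variance-stabilized layer restricted to highly variable genes, a Jaccard-
weighted k-nearest-neighbour graph in PC space, and Leiden community
detection with the RBConfiguration (modularity-with-resolution) objective.
Cluster labels are renumbered by decreasing size, ties broken by the first
cell index, so labelings are stable across runs with the same seed.

Marker detection uses the two-sided Wilcoxon rank-sum test on lognorm
values, cluster versus all other cells, with a detection-percentage and
log-fold-change pre-filter, followed by Benjamini–Hochberg correction
across all tests performed.  For small groups (both sides ≤ 8 cells) the
p-value is computed by exhaustive enumeration of the permutation
distribution of the rank sum — exact even in the presence of ties —
otherwise by the tie-corrected normal approximation (no continuity
correction).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from crossortho.errors import ConfigError, PipelineError
from crossortho.qc_normalize import NormalizedMatrix

logger = logging.getLogger(__name__)

_EXACT_MAX_GROUP = 8  # exhaustive enumeration bound for the rank-sum test


@dataclass
class ClusterParams:
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ConfigError("n_pcs must be ≥ 2")
        if self.k_neighbors < 2:
            raise ConfigError("k_neighbors must be ≥ 2")
        if self.resolution <= 0:
            raise ConfigError("resolution must be > 0")


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels 0..C−1, numbered by decreasing cluster size."""

    cluster_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_of_cell = np.asarray(self.cluster_of_cell, dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_of_cell))

    def cells_of(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of_cell == cluster)


@dataclass
class DEParams:
    min_pct: float = 0.10
    min_logfc: float = 0.25  # natural-log scale
    alpha: float = 0.05
    pseudocount: float = 1e-9

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pct <= 1.0):
            raise ConfigError("min_pct must be in [0,1]")
        if self.min_logfc < 0 or self.pseudocount < 0:
            raise ConfigError("min_logfc and pseudocount must be ≥ 0")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0,1)")


def renumber_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber arbitrary labels by decreasing size, ties by first index."""
    raw = np.asarray(raw)
    uniq, first_idx, counts = {}, {}, {}
    for i, lab in enumerate(raw):
        if lab not in uniq:
            uniq[lab] = True
            first_idx[lab] = i
            counts[lab] = 0
        counts[lab] += 1
    order = sorted(counts, key=lambda lab: (-counts[lab], first_idx[lab]))
    mapping = {lab: new for new, lab in enumerate(order)}
    return np.array([mapping[lab] for lab in raw], dtype=int)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def reduce_pca(
    nm: NormalizedMatrix, genes: np.ndarray | list[int] | None, n_pcs: int
) -> np.ndarray:
    """Principal components of the gene-centered cell×gene matrix.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so the embedding is deterministic.
    Returns a cell × n_pcs array ordered by decreasing explained variance.
    """
    genes = np.arange(nm.n_genes) if genes is None else np.asarray(genes)
    X = nm.values[genes, :]
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float).T  # cells × genes
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise PipelineError("PCA requires at least 2 cells")
    if n_pcs > min(n_genes, n_cells):
        raise ConfigError(
            f"n_pcs={n_pcs} exceeds min(n_genes={n_genes}, n_cells={n_cells})"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # loading-based deterministic sign flip
    for j in range(n_pcs):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U[:, :n_pcs] * S[:n_pcs]


def explained_variance(nm: NormalizedMatrix, genes, n_pcs: int) -> np.ndarray:
    """Variance explained per PC (for diagnostics)."""
    emb = reduce_pca(nm, genes, n_pcs)
    return emb.var(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# kNN graph + Leiden
# ---------------------------------------------------------------------------


def build_knn_graph(emb: np.ndarray, k: int) -> ig.Graph:
    """Jaccard-weighted union-of-kNN graph over cells.

    Each cell's neighbour set is its ``k`` Euclidean nearest neighbours
    (self excluded).  An undirected edge joins every ordered neighbour
    relation; its weight is the Jaccard overlap of the two endpoint
    neighbour sets.  Zero-weight edges are dropped; no self-loops.
    """
    emb = np.asarray(emb, dtype=float)
    n = emb.shape[0]
    if k >= n:
        raise ConfigError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neighbor_sets: list[set[int]] = []
    for i in range(n):
        s = set(int(j) for j in idx[i] if j != i)
        while len(s) > k:  # can't happen, defensive
            s.pop()
        if len(s) < k:  # self not in the k+1 ring (exact duplicates)
            extra = [int(j) for j in idx[i] if int(j) != i]
            s = set(extra[:k])
        neighbor_sets.append(s)
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        for j in neighbor_sets[i]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neighbor_sets[a] & neighbor_sets[b])
            union = len(neighbor_sets[a] | neighbor_sets[b])
            w = inter / union if union else 0.0
            if w > 0:
                edges.append((a, b))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    return g


def cluster_graph(graph: ig.Graph, resolution: float, seed: int) -> ClusterAssignment:
    """Leiden community detection (RBConfiguration objective) on the graph."""
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return ClusterAssignment(renumber_labels(np.asarray(part.membership)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Exact (exhaustive enumeration, tie-aware) when both groups have ≤ 8
    observations; tie-corrected normal approximation otherwise.  The
    two-sided exact p is ``P(|S − E[S]| ≥ |s_obs − E[S]|)`` over all
    equally likely assignments of the pooled values to the two groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise PipelineError("empty group in rank-sum test")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    s_obs = ranks[:n1].sum()
    if n1 <= _EXACT_MAX_GROUP and n2 <= _EXACT_MAX_GROUP:
        return _exact_rank_sum_p(ranks, n1, s_obs)
    return _asymptotic_rank_sum_p(ranks, n1, s_obs)


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, s_obs: float) -> float:
    n = len(ranks)
    mu = n1 * (n + 1) / 2.0
    dev = abs(s_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def _asymptotic_rank_sum_p(ranks: np.ndarray, n1: int, s_obs: float) -> float:
    n = len(ranks)
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return 1.0
    z = (s_obs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# marker ranking
# ---------------------------------------------------------------------------


def _group_stats(dense: np.ndarray, mask: np.ndarray, pseudo: float):
    """Detection fraction and mean expm1 expression for one cell group."""
    sub = dense[:, mask]
    pct = (sub > 0).mean(axis=1)
    mean_expm1 = np.expm1(sub).mean(axis=1)
    return pct, mean_expm1 + pseudo


def rank_markers(
    nm: NormalizedMatrix,
    ca: ClusterAssignment,
    p: DEParams | None = None,
    mode: str = "one_vs_rest",
) -> pd.DataFrame:
    """Per-cluster differential expression of lognorm values.

    A gene enters testing for a cluster when it is detected in at least
    ``min_pct`` of either the cluster or the rest AND its |log fold
    change| (natural log of the ratio of group means of ``expm1`` lognorm
    values, pseudocount added inside the means) is at least ``min_logfc``.
    Benjamini–Hochberg correction spans all tests performed across
    clusters.  Rows are sorted by (cluster, q, −log_fc).

    ``mode="pairwise_subtypes"`` additionally restricts each comparison to
    cluster-vs-single-other-cluster contrasts; a row is kept only when the
    gene passes the pre-filter against *every* other cluster, and the
    reported p-value is the maximum over those contrasts (the most
    conservative), so "marker" means elevated against each subtype
    separately.
    """
    if p is None:
        p = DEParams()
    if nm.layer != "lognorm":
        raise PipelineError("rank_markers expects the lognorm layer")
    labels = ca.cluster_of_cell
    if len(labels) != nm.n_cells:
        raise PipelineError("cluster assignment does not match matrix cells")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise PipelineError("rank_markers needs ≥ 2 clusters")
    sizes = {int(c): int((labels == c).sum()) for c in clusters}
    too_small = [c for c, s in sizes.items() if s < 3]
    if too_small:
        raise PipelineError(
            f"clusters below the 3-cell floor: {sorted(too_small)}"
        )

    dense = nm.dense()
    rows: list[dict] = []
    if mode == "one_vs_rest":
        # cluster-vs-rest partitions the full cell set, so one ranking of
        # all cells per gene serves every cluster
        all_ranks = stats.rankdata(dense, axis=1)
        n = dense.shape[1]
        for c in clusters:
            mask = labels == c
            n1 = int(mask.sum())
            n2 = n - n1
            pct_in, mean_in = _group_stats(dense, mask, p.pseudocount)
            pct_out, mean_out = _group_stats(dense, ~mask, p.pseudocount)
            log_fc = np.log(mean_in / mean_out)
            tested = ((pct_in >= p.min_pct) | (pct_out >= p.min_pct)) & (
                np.abs(log_fc) >= p.min_logfc
            )
            gene_idx = np.flatnonzero(tested)
            if gene_idx.size == 0:
                continue
            if n1 <= _EXACT_MAX_GROUP and n2 <= _EXACT_MAX_GROUP:
                pvals = np.array(
                    [
                        wilcoxon_rank_sum_p(dense[g, mask], dense[g, ~mask])
                        for g in gene_idx
                    ]
                )
            else:
                pvals = _vectorized_asymptotic(
                    dense[gene_idx], all_ranks[gene_idx], mask
                )
            for g, pv in zip(gene_idx, pvals):
                rows.append(
                    {
                        "cluster": int(c),
                        "gene_id": nm.gene_ids[g],
                        "symbol": nm.gene_symbols[g],
                        "log_fc": float(log_fc[g]),
                        "p_value": float(pv),
                        "pct_in": float(pct_in[g]),
                        "pct_out": float(pct_out[g]),
                    }
                )
    elif mode == "pairwise_subtypes":
        for c in clusters:
            mask_c = labels == c
            pct_in, mean_in = _group_stats(dense, mask_c, p.pseudocount)
            keep = np.ones(nm.n_genes, dtype=bool)
            worst_p = np.zeros(nm.n_genes)
            min_lfc = np.full(nm.n_genes, np.inf)
            for other in clusters:
                if other == c:
                    continue
                mask_o = labels == other
                pct_o, mean_o = _group_stats(dense, mask_o, p.pseudocount)
                lfc = np.log(mean_in / mean_o)
                tested = ((pct_in >= p.min_pct) | (pct_o >= p.min_pct)) & (
                    lfc >= p.min_logfc
                )
                keep &= tested
                idx = np.flatnonzero(keep)
                for g in idx:
                    pv = wilcoxon_rank_sum_p(dense[g, mask_c], dense[g, mask_o])
                    worst_p[g] = max(worst_p[g], pv)
                min_lfc[np.flatnonzero(keep)] = np.minimum(
                    min_lfc[np.flatnonzero(keep)], lfc[np.flatnonzero(keep)]
                )
            pct_out_all = (dense[:, ~mask_c] > 0).mean(axis=1)
            for g in np.flatnonzero(keep):
                rows.append(
                    {
                        "cluster": int(c),
                        "gene_id": nm.gene_ids[g],
                        "symbol": nm.gene_symbols[g],
                        "log_fc": float(min_lfc[g]),
                        "p_value": float(worst_p[g]),
                        "pct_in": float(pct_in[g]),
                        "pct_out": float(pct_out_all[g]),
                    }
                )
    else:
        raise ConfigError(f"unknown mode {mode!r}")

    df = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "gene_id",
            "symbol",
            "log_fc",
            "p_value",
            "pct_in",
            "pct_out",
        ],
    )
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(
            ["cluster", "q_value", "log_fc"],
            ascending=[True, True, False],
            kind="mergesort",
        ).reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    df.attrs["clusters"] = [int(c) for c in clusters]
    df.attrs["mode"] = mode
    return df


def _vectorized_asymptotic(
    dense_sub: np.ndarray, ranks_sub: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p, vectorized over genes."""
    n = dense_sub.shape[1]
    n1 = int(mask.sum())
    n2 = n - n1
    s = ranks_sub[:, mask].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie_terms = np.empty(dense_sub.shape[0])
    for i in range(dense_sub.shape[0]):
        _, t = np.unique(dense_sub[i], return_counts=True)
        tie_terms[i] = (t.astype(float) ** 3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1.0)))
    p = np.ones(dense_sub.shape[0])
    ok = var > 0
    z = np.zeros_like(p)
    z[ok] = (s[ok] - mu) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return np.minimum(p, 1.0)


def sample_composition(ca: ClusterAssignment, sample_of_cell) -> pd.DataFrame:
    """Cluster × sample cell-count table (replicate-bias eyeball check)."""
    return pd.crosstab(
        pd.Series(ca.cluster_of_cell, name="cluster"),
        pd.Series(list(sample_of_cell), name="sample"),
    )
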