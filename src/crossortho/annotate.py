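"""Marker-panel scoring of clusters and cell-type assignment.

Annotation formalizes the dot-plot logic used when curating testis cell
types by eye: for each cluster and each marker panel, compute the mean
fraction of the cluster's cells detecting each panel gene (count > 0),
averaged over the panel genes present in the data, then z-score that
detection fraction across clusters per panel.  Each cluster receives the
label of its argmax-score panel, unless the margin to the runner-up falls
below ``min_margin``, in which case it is labeled ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from crossortho.errors import PipelineError
from crossortho.cluster_de import ClusterAssignment, ClusterParams
from crossortho.io_tenx import CountMatrix, MarkerPanelSet
from crossortho.qc_normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class PanelScoreMatrix:
    detection_fraction: pd.DataFrame  # cluster × panel
    score: pd.DataFrame  # cluster × panel, z-scored per panel
    missing_genes: dict[str, list[str]]
    skipped_panels: list[str] = field(default_factory=list)


@dataclass
class CellTypeLabels:
    """Cluster-level labels: cluster → (label, score, margin to runner-up)."""

    label_of_cluster: dict[int, tuple[str, float, float]]
    level: str

    def label(self, cluster: int) -> str:
        return self.label_of_cluster[cluster][0]

    def clusters_with_label(self, label: str) -> list[int]:
        return [c for c, (lab, _, _) in self.label_of_cluster.items() if lab == label]

    def labels_of_cells(self, ca: ClusterAssignment) -> np.ndarray:
        return np.array([self.label(int(c)) for c in ca.cluster_of_cell])


def score_marker_panels(
    nm: NormalizedMatrix, ca: ClusterAssignment, panels: MarkerPanelSet
) -> PanelScoreMatrix:
    """Detection-fraction and z-score of each panel in each cluster.

    Panel genes are matched by symbol, case-insensitively.  Panels with no
    matched gene are skipped (and reported); needs ≥ 2 clusters for the
    z-score to be defined.
    """
    clusters = np.unique(ca.cluster_of_cell)
    if len(clusters) < 2:
        raise PipelineError("panel z-scores need ≥ 2 clusters")
    sym_to_rows: dict[str, list[int]] = {}
    for i, s in enumerate(nm.gene_symbols):
        sym_to_rows.setdefault(s.lower(), []).append(i)

    X = nm.values
    detected = (X > 0) if sp.issparse(X) else (np.asarray(X) > 0)
    if sp.issparse(detected):
        detected = sp.csr_matrix(detected)

    # per-gene detection fraction per cluster
    det_frac = {}
    for c in clusters:
        mask = ca.cluster_of_cell == c
        sub = detected[:, mask]
        frac = (
            np.asarray(sub.mean(axis=1)).ravel()
            if sp.issparse(sub)
            else sub.mean(axis=1)
        )
        det_frac[int(c)] = frac

    missing: dict[str, list[str]] = {}
    skipped: list[str] = []
    cols: dict[str, np.ndarray] = {}
    for label, genes in panels.panels.items():
        rows: list[int] = []
        miss: list[str] = []
        for g in genes:
            hit = sym_to_rows.get(g.lower())
            if hit:
                rows.extend(hit)
            else:
                miss.append(g)
        missing[label] = miss
        if not rows:
            skipped.append(label)
            logger.warning("panel %r: no genes present, skipped", label)
            continue
        cols[label] = np.array(
            [det_frac[int(c)][rows].mean() for c in clusters]
        )
    if not cols:
        raise PipelineError("no marker panel had any gene in the matrix")
    frac_df = pd.DataFrame(cols, index=[int(c) for c in clusters])
    mean = frac_df.mean(axis=0)
    std = frac_df.std(axis=0, ddof=0)
    score_df = (frac_df - mean) / std.replace(0.0, np.nan)
    score_df = score_df.fillna(0.0)
    return PanelScoreMatrix(
        detection_fraction=frac_df,
        score=score_df,
        missing_genes=missing,
        skipped_panels=skipped,
    )


def assign_cell_types(
    ps: PanelScoreMatrix, level: str, min_margin: float = 0.5
) -> CellTypeLabels:
    """Argmax-panel labeling with a margin rule.

    A cluster whose top-two score margin is below ``min_margin`` is labeled
    ``"ambiguous"`` (germ_subtype level) or ``"other"``.  Exact ties break
    toward the earlier panel in config order with a logged warning.
    """
    fallback = "ambiguous" if level == "germ_subtype" else "other"
    out: dict[int, tuple[str, float, float]] = {}
    panel_order = list(ps.score.columns)
    for cluster, row in ps.score.iterrows():
        scores = row.to_numpy(dtype=float)
        best = int(np.argmax(scores))  # first occurrence wins ties
        top = float(scores[best])
        if len(scores) > 1:
            rest = np.delete(scores, best)
            margin = top - float(rest.max())
        else:
            margin = float("inf")
        if np.sum(scores == top) > 1:
            logger.warning(
                "cluster %s: exact panel-score tie, keeping %r (config order)",
                cluster,
                panel_order[best],
            )
        label = panel_order[best] if margin >= min_margin else fallback
        out[int(cluster)] = (label, top, max(margin, 0.0))
    return CellTypeLabels(label_of_cluster=out, level=level)


def extract_and_recluster(
    m: CountMatrix,
    ca: ClusterAssignment,
    labels: CellTypeLabels,
    target_label: str,
    params: ClusterParams,
    *,
    n_hvg: int = 2000,
    min_cells: int = 20,
) -> tuple[CountMatrix, ClusterAssignment]:
    """Subset cells of clusters carrying ``target_label`` and re-cluster.

    The focused analysis re-runs the whole route — normalization, HVG
    selection, PCA, kNN graph, Leiden — on the subset, so finer structure
    invisible in the full dataset can emerge (the germ-cell use case).
    """
    from crossortho.pipeline import cluster_workflow

    target_clusters = set(labels.clusters_with_label(target_label))
    mask = np.array([int(c) in target_clusters for c in ca.cluster_of_cell])
    n = int(mask.sum())
    if n < min_cells:
        raise PipelineError(
            f"only {n} cells carry label {target_label!r} (minimum {min_cells})"
        )
    sub = CountMatrix(
        species=m.species,
        counts=sp.csr_matrix(m.counts)[:, mask],
        gene_ids=list(m.gene_ids),
        gene_symbols=list(m.gene_symbols),
        cell_barcodes=[b for b, k in zip(m.cell_barcodes, mask) if k],
        sample_of_cell=[s for s, k in zip(m.sample_of_cell, mask) if k],
    )
    # drop genes that vanished from the subset so normalization is well posed
    nonzero = np.asarray((sub.counts > 0).sum(axis=1)).ravel() > 0
    sub = CountMatrix(
        species=sub.species,
        counts=sub.counts[nonzero, :],
        gene_ids=[g for g, k in zip(sub.gene_ids, nonzero) if k],
        gene_symbols=[s for s, k in zip(sub.gene_symbols, nonzero) if k],
        cell_barcodes=sub.cell_barcodes,
        sample_of_cell=sub.sample_of_cell,
    )
    wf = cluster_workflow(sub, params, n_hvg=n_hvg)
    return sub, wf.assignment
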