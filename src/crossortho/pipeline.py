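"""End-to-end workflows composing the pipeline stages.

These helpers run the standard per-species route (QC → lognorm + Pearson
residuals → HVG → PCA → kNN graph → Leiden) and the cross-species stage
(ortholog harmonization → merged lognorm matrices → cluster-average
profiles → correlation anchoring → conserved-marker intersection).  The
CLI, the test fixtures and the acceptance script all drive these same
functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossortho.annotate import (
    CellTypeLabels,
    assign_cell_types,
    score_marker_panels,
)
from crossortho.cluster_de import (
    ClusterAssignment,
    ClusterParams,
    DEParams,
    build_knn_graph,
    cluster_graph,
    rank_markers,
    reduce_pca,
)
from crossortho.conserved_markers import (
    ConservedMarkerSet,
    intersect_marker_sets,
    ssc_markers_for_species,
)
from crossortho.crosspecies import (
    OrthologMap,
    anchor_groups,
    average_profiles,
    correlate_profiles,
    harmonize_orthologs,
    merge_on_orthologs,
)
from crossortho.errors import PipelineError
from crossortho.io_tenx import CountMatrix, MarkerPanelSet, OrthologTable
from crossortho.qc_normalize import (
    NormalizedMatrix,
    QCParams,
    QCReport,
    filter_counts,
    normalize_log,
    pearson_residuals,
    select_hvg,
)


@dataclass
class ClusterWorkflowResult:
    lognorm: NormalizedMatrix
    residuals: NormalizedMatrix
    hvg: np.ndarray
    embedding: np.ndarray
    assignment: ClusterAssignment


@dataclass
class SpeciesResult:
    """Everything the per-species stages produce for one species."""

    counts: CountMatrix
    qc_report: QCReport
    workflow: ClusterWorkflowResult
    labels: CellTypeLabels | None = None
    de: pd.DataFrame | None = None

    @property
    def lognorm(self) -> NormalizedMatrix:
        return self.workflow.lognorm

    @property
    def assignment(self) -> ClusterAssignment:
        return self.workflow.assignment


def cluster_workflow(
    m: CountMatrix,
    params: ClusterParams,
    *,
    n_hvg: int = 2000,
    scale_factor: float = 1e4,
    theta: float = 100.0,
) -> ClusterWorkflowResult:
    """Normalize, select HVGs, embed and cluster one count matrix."""
    lognorm = normalize_log(m, scale_factor)
    resid = pearson_residuals(m, theta=theta)
    hvg = select_hvg(resid, min(n_hvg, m.n_genes))
    n_pcs = min(params.n_pcs, len(hvg), m.n_cells - 1)
    emb = reduce_pca(resid, hvg, n_pcs)
    k = min(params.k_neighbors, m.n_cells - 1)
    graph = build_knn_graph(emb, k)
    ca = cluster_graph(graph, params.resolution, params.seed)
    return ClusterWorkflowResult(
        lognorm=lognorm,
        residuals=resid,
        hvg=hvg,
        embedding=emb,
        assignment=ca,
    )


def run_species(
    m: CountMatrix,
    qc: QCParams | None = None,
    cluster_params: ClusterParams | None = None,
    panels: MarkerPanelSet | None = None,
    *,
    n_hvg: int = 2000,
    min_margin: float = 0.5,
) -> SpeciesResult:
    """QC, cluster and (optionally) annotate one species."""
    qc = qc or QCParams()
    cluster_params = cluster_params or ClusterParams()
    filtered, report = filter_counts(m, qc)
    wf = cluster_workflow(filtered, cluster_params, n_hvg=n_hvg)
    labels = None
    if panels is not None:
        ps = score_marker_panels(wf.lognorm, wf.assignment, panels)
        labels = assign_cell_types(ps, panels.level, min_margin=min_margin)
    return SpeciesResult(
        counts=filtered, qc_report=report, workflow=wf, labels=labels
    )


@dataclass
class CrossSpeciesResult:
    omap: OrthologMap
    merged: dict[str, NormalizedMatrix]
    profiles: dict[str, pd.DataFrame]
    correlations: dict[tuple[str, str], pd.DataFrame]
    anchors: dict[tuple[str, str], object]


def run_cross_species(
    results: dict[str, SpeciesResult],
    tables: list[OrthologTable],
    reference_species: str,
    *,
    groups_of: dict[str, np.ndarray] | None = None,
    mean_of_expm1: bool = False,
) -> CrossSpeciesResult:
    """Harmonize orthologs, build profiles, and anchor all species pairs.

    ``groups_of`` overrides the per-species grouping (defaults to the
    Leiden cluster assignment); supply cell-type label arrays to anchor
    annotated types instead of unbiased clusters.
    """
    omap = harmonize_orthologs(tables, reference_species)
    merged = merge_on_orthologs([r.lognorm for r in results.values()], omap)
    profiles = {}
    for species, r in results.items():
        groups = (
            groups_of[species]
            if groups_of is not None
            else r.assignment.cluster_of_cell
        )
        profiles[species] = average_profiles(
            merged[species], groups, mean_of_expm1=mean_of_expm1
        )
    species_list = list(results)
    correlations = {}
    anchors = {}
    for a in species_list:
        for b in species_list:
            if a == b:
                continue
            cm = correlate_profiles(profiles[a], profiles[b])
            correlations[(a, b)] = cm
            anchors[(a, b)] = anchor_groups(cm)
    return CrossSpeciesResult(
        omap=omap,
        merged=merged,
        profiles=profiles,
        correlations=correlations,
        anchors=anchors,
    )


def conserved_ssc_markers(
    results: dict[str, SpeciesResult],
    omap: OrthologMap,
    ssc_group_of: dict[str, object],
    de_params: DEParams | None = None,
    *,
    group_labels_of: dict[str, np.ndarray] | None = None,
) -> tuple[ConservedMarkerSet, dict[str, set[str]]]:
    """Derive per-species SSC marker sets and intersect them.

    DE runs one-vs-rest over the germ-subtype grouping of each species
    (``group_labels_of`` overrides the cluster assignment when supplied;
    group ids must then match ``ssc_group_of``).
    """
    de_params = de_params or DEParams()
    per_species: dict[str, set[str]] = {}
    evidence: dict[str, pd.DataFrame] = {}
    for species, r in results.items():
        if group_labels_of is not None:
            groups = ClusterAssignment(np.asarray(group_labels_of[species]))
        else:
            groups = r.assignment
        de = rank_markers(r.lognorm, groups, de_params, mode="one_vs_rest")
        r.de = de
        per_species[species] = ssc_markers_for_species(
            de, ssc_group_of[species], de_params
        )
        evidence[species] = de[de["cluster"] == ssc_group_of[species]]
    conserved = intersect_marker_sets(per_species, omap, evidence)
    return conserved, per_species


def majority_vote_accuracy(
    ca: ClusterAssignment, truth: np.ndarray
) -> tuple[float, dict[int, int]]:
    """Accuracy of the cluster → majority-true-type mapping, plus the map."""
    truth = np.asarray(truth)
    if len(truth) != len(ca.cluster_of_cell):
        raise PipelineError("truth labels do not match assignment")
    mapping: dict[int, int] = {}
    correct = 0
    for c in np.unique(ca.cluster_of_cell):
        mask = ca.cluster_of_cell == c
        vals, counts = np.unique(truth[mask], return_counts=True)
        maj = int(vals[np.argmax(counts)])
        mapping[int(c)] = maj
        correct += int((truth[mask] == maj).sum())
    return correct / len(truth), mapping
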