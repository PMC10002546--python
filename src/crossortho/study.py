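"""Reference study conditions: the end-to-end synthetic benchmark.

Runs the whole pipeline — simulation, QC, clustering, panel annotation,
ortholog harmonization, correlation anchoring and conserved-marker
intersection — under the package's reference conditions (three species,
five shared cell types, 2,000 ortholog genes, 900 cells per species,
2.5-fold planted markers, NB theta 10) and scores the results against the
planted ground truth.  Planted type 0 is the SSC-like state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from crossortho.cluster_de import ClusterParams, DEParams
from crossortho.pipeline import (
    CrossSpeciesResult,
    SpeciesResult,
    conserved_ssc_markers,
    majority_vote_accuracy,
    run_cross_species,
    run_species,
)
from crossortho.qc_normalize import QCParams
from crossortho.synthetic import (
    SimulationConfig,
    SyntheticGroundTruth,
    generate_dataset,
)

SSC_TYPE = 0  # planted type treated as the SSC-like state


@dataclass
class StudyRun:
    seed: int
    truth: SyntheticGroundTruth
    results: dict[str, SpeciesResult]
    kept_truth: dict[str, np.ndarray]  # planted types of QC-surviving cells
    cross: CrossSpeciesResult
    conserved_genes: set[str]
    per_species_marker_sets: dict[str, set[str]]
    metrics: dict[str, float] = field(default_factory=dict)


def run_reference_study(seed: int, **sim_overrides) -> StudyRun:
    """Run the full pipeline on one simulated replicate and score it."""
    sim = SimulationConfig(seed=seed, **sim_overrides)
    matrices, tables, truth = generate_dataset(sim)
    reference = sim.species_names[0]

    results: dict[str, SpeciesResult] = {}
    kept_truth: dict[str, np.ndarray] = {}
    for m in matrices:
        r = run_species(
            m, QCParams(), ClusterParams(seed=seed), panels=truth.panels
        )
        results[m.species] = r
        idx_of = {b: i for i, b in enumerate(m.cell_barcodes)}
        kept = [idx_of[b] for b in r.counts.cell_barcodes]
        kept_truth[m.species] = truth.true_type_of_cell[m.species][kept]

    cross = run_cross_species(results, tables, reference)

    # cluster → majority planted type, per species
    type_of_cluster: dict[str, dict[int, int]] = {}
    cluster_acc: dict[str, float] = {}
    for s, r in results.items():
        acc, mapping = majority_vote_accuracy(r.assignment, kept_truth[s])
        cluster_acc[s] = acc
        type_of_cluster[s] = mapping

    # anchoring recovery: every cluster anchors to a cluster of its own type
    n_ok = n_tot = 0
    sep_margins = []
    for (a, b), anchors in cross.anchors.items():
        for cl, row in anchors.assignments.iterrows():
            n_tot += 1
            if type_of_cluster[a][int(cl)] == type_of_cluster[b][int(row["best"])]:
                n_ok += 1
        cm = cross.correlations[(a, b)]
        same, diff = [], []
        for i in cm.index:
            for j in cm.columns:
                (same if type_of_cluster[a][int(i)] == type_of_cluster[b][int(j)] else diff).append(
                    cm.loc[i, j]
                )
        if same and diff:
            sep_margins.append(min(same) - max(diff))

    # SSC labeling: exactly the planted-type-0 clusters labeled SSC everywhere
    ssc_label_ok = True
    group_labels: dict[str, np.ndarray] = {}
    ssc_group_of: dict[str, int] = {}
    for s, r in results.items():
        labs = r.labels.labels_of_cells(r.assignment)
        ssc_clusters = set(r.labels.clusters_with_label("SSC"))
        planted_clusters = {
            c for c, t in type_of_cluster[s].items() if t == SSC_TYPE
        }
        if ssc_clusters != planted_clusters:
            ssc_label_ok = False
        uniq = sorted(set(labs))
        idx = {lab: i for i, lab in enumerate(uniq)}
        group_labels[s] = np.array([idx[lab] for lab in labs])
        ssc_group_of[s] = idx.get("SSC", -1)

    conserved_genes: set[str] = set()
    per_sets: dict[str, set[str]] = {s: set() for s in results}
    precision = recall = 0.0
    leakage = 0
    if all(g >= 0 for g in ssc_group_of.values()):
        conserved, per_sets = conserved_ssc_markers(
            results,
            cross.omap,
            ssc_group_of,
            DEParams(),
            group_labels_of=group_labels,
        )
        conserved_genes = set(conserved.genes)
        planted = truth.conserved_markers_of_type[SSC_TYPE]
        if conserved_genes:
            precision = len(conserved_genes & planted) / len(conserved_genes)
        recall = len(conserved_genes & planted) / len(planted)
        for s in results:
            ev = conserved.evidence
            native = set(ev[ev["species"] == s]["native_id"])
            leakage += len(native & truth.species_specific_markers[(s, SSC_TYPE)])

    metrics = {
        "anchoring_accuracy": n_ok / n_tot if n_tot else 0.0,
        "correlation_separation": min(sep_margins) if sep_margins else float("nan"),
        "clustering_accuracy": min(cluster_acc.values()),
        "ssc_label_correct": float(ssc_label_ok),
        "conserved_precision": precision,
        "conserved_recall": recall,
        "species_specific_leakage": float(leakage),
        "n_conserved_markers": float(len(conserved_genes)),
        "cells_after_qc": float(
            sum(r.qc_report.cells_out for r in results.values())
        ),
        "n_ortholog_map_genes": float(len(cross.omap.rows)),
    }
    return StudyRun(
        seed=seed,
        truth=truth,
        results=results,
        kept_truth=kept_truth,
        cross=cross,
        conserved_genes=conserved_genes,
        per_species_marker_sets=per_sets,
        metrics=metrics,
    )
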