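"""Per-species SSC marker derivation and cross-species intersection.

A species' SSC marker set is the genes significantly up-regulated
(q < alpha, log fold change > min_logfc) in the SSC group versus the other
spermatogonial subtypes.  Mapping each species' native gene ids through the
strict one-to-one ortholog map and intersecting across species yields the
conserved marker set — the cross-species SSC signature.  A profile table
of selected genes across the germ-cell subtypes supports relating the
molecular states to the histological A_dark/A_pale classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crossortho.errors import PipelineError
from crossortho.annotate import CellTypeLabels
from crossortho.cluster_de import DEParams
from crossortho.crosspecies import OrthologMap
from crossortho.qc_normalize import NormalizedMatrix

logger = logging.getLogger(__name__)

# A_dark markers (EXOSC10, FGFR3) and A_pale markers (MKI67, DMRT1)
DEFAULT_PROFILE_GENES = ["EXOSC10", "FGFR3", "MKI67", "DMRT1"]

GERM_SUBTYPE_ORDER = ["SSC", "progenitor", "differentiating", "late_differentiating"]


@dataclass
class ConservedMarkerSet:
    """Genes marking the same cell type in every required species."""

    genes: list[str]  # reference gene ids
    evidence: pd.DataFrame  # columns: gene, species, native_id, log_fc, q_value
    n_species_required: int


def ssc_markers_for_species(
    de: pd.DataFrame, ssc_group, p: DEParams | None = None
) -> set[str]:
    """Native ids of genes up in the SSC group at the DE thresholds."""
    if p is None:
        p = DEParams()
    known = de.attrs.get("clusters")
    if known is not None and ssc_group not in known:
        raise PipelineError(
            f"group {ssc_group!r} absent from DE result (has {known})"
        )
    sub = de[de["cluster"] == ssc_group]
    if known is None and sub.empty and ssc_group not in set(de["cluster"]):
        raise PipelineError(f"group {ssc_group!r} absent from DE result")
    hits = sub[(sub["log_fc"] > p.min_logfc) & (sub["q_value"] < p.alpha)]
    return set(hits["gene_id"])


def intersect_marker_sets(
    sets: dict[str, set[str]],
    omap: OrthologMap,
    evidence: dict[str, pd.DataFrame] | None = None,
) -> ConservedMarkerSet:
    """Map per-species native-id marker sets to reference ids and intersect.

    Native ids with no row in the ortholog map are dropped (counted in a
    warning).  The intersection is commutative in species order; an empty
    result is allowed.
    """
    if len(sets) < 2:
        raise PipelineError("need marker sets from ≥ 2 species")
    mapped: dict[str, set[str]] = {}
    for species, native in sets.items():
        to_ref = omap.native_to_reference(species)
        ref = {to_ref[g] for g in native if g in to_ref}
        dropped = len(native) - len({g for g in native if g in to_ref})
        if dropped:
            logger.warning(
                "intersect_marker_sets(%s): %d native ids not in ortholog map",
                species,
                dropped,
            )
        if not ref:
            logger.warning(
                "intersect_marker_sets(%s): no marker maps to a reference id",
                species,
            )
        mapped[species] = ref
    common: set[str] | None = None
    for ref in mapped.values():
        common = ref if common is None else (common & ref)
    genes = sorted(common or set())

    rows = []
    for species in sets:
        ref_of = dict(zip(omap.rows.index, omap.rows[species]))
        ev = evidence.get(species) if evidence else None
        for g in genes:
            native_id = ref_of[g]
            rec = {"gene": g, "species": species, "native_id": native_id}
            if ev is not None:
                hit = ev[ev["gene_id"] == native_id]
                if len(hit):
                    rec["log_fc"] = float(hit["log_fc"].iloc[0])
                    rec["q_value"] = float(hit["q_value"].iloc[0])
            rows.append(rec)
    evidence_df = pd.DataFrame(
        rows, columns=["gene", "species", "native_id", "log_fc", "q_value"]
    )
    return ConservedMarkerSet(
        genes=genes, evidence=evidence_df, n_species_required=len(sets)
    )


def marker_profile(
    nm: NormalizedMatrix,
    labels: CellTypeLabels | np.ndarray | list,
    genes: list[str] | None = None,
    *,
    type_order: list[str] | None = None,
    cluster_assignment=None,
) -> pd.DataFrame:
    """Mean lognorm expression of selected genes per cell type, plus a
    per-gene row-scaled (z-scored) layer for heatmap export.

    ``genes`` are matched by symbol, case-insensitively; the default list
    profiles the A_dark (EXOSC10, FGFR3) versus A_pale (MKI67, DMRT1)
    discriminators across SSC → progenitor → differentiating →
    late-differentiating spermatogonia.
    """
    if genes is None:
        genes = list(DEFAULT_PROFILE_GENES)
    if type_order is None:
        type_order = list(GERM_SUBTYPE_ORDER)
    if isinstance(labels, CellTypeLabels):
        if cluster_assignment is None:
            raise PipelineError(
                "cluster_assignment required when labels are cluster-level"
            )
        cell_labels = labels.labels_of_cells(cluster_assignment)
    else:
        cell_labels = np.asarray(labels)

    sym_to_row: dict[str, int] = {}
    for i, s in enumerate(nm.gene_symbols):
        sym_to_row.setdefault(s.lower(), i)
    present = [(g, sym_to_row[g.lower()]) for g in genes if g.lower() in sym_to_row]
    if not present:
        raise PipelineError(f"none of the requested genes present: {genes}")

    X = nm.dense()
    types = [t for t in type_order if (cell_labels == t).any()]
    if not types:
        raise PipelineError("no cell carries any of the requested cell types")
    records = []
    for g, row in present:
        means = np.array(
            [X[row, cell_labels == t].mean() for t in types], dtype=float
        )
        sd = means.std(ddof=0)
        z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
        for t, m, zz in zip(types, means, z):
            records.append({"gene": g, "cell_type": t, "mean": m, "z": zz})
    return pd.DataFrame(records, columns=["gene", "cell_type", "mean", "z"])
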