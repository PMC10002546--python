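"""Ortholog harmonization and correlation-based cross-species anchoring.

This is the pipeline's core inference.  Pairwise Biomart-style ortholog
tables (each relating the reference species to one other species) are
reduced to a strict one-to-one-…-to-one map: within each pairwise table,
any gene participating in more than one row is discarded outright (a
paralog or ambiguous mapping), and only reference genes surviving every
table are kept.  Expression matrices are then re-indexed to the shared
reference gene order, cluster-average expression profiles are computed,
and clusters are anchored across species by the Pearson correlation of
those profiles: each cluster maps to its most-correlated counterpart, with
the margin to the runner-up and a tie flag reported.

Correlations are computed over all mapped ortholog genes on lognorm
cluster means by default (a mean-of-expm1 alternative is available), and a
zero-variance profile correlates 0 with everything (with a warning) so the
anchoring remains total.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from crossortho.errors import PipelineError
from crossortho.cluster_de import ClusterAssignment
from crossortho.io_tenx import OrthologTable
from crossortho.qc_normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Strict 1-1-…-1 gene correspondence keyed by the reference species.

    ``rows`` is a DataFrame indexed by reference gene id with one column
    per species (the reference species maps to itself).
    """

    reference_species: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        for col in self.rows.columns:
            vals = self.rows[col]
            if vals.duplicated().any():
                raise PipelineError(
                    f"ortholog map not one-to-one in species {col!r}"
                )
        if self.rows.isna().any().any():
            raise PipelineError("ortholog map has incomplete rows")

    @property
    def species(self) -> list[str]:
        return list(self.rows.columns)

    @property
    def reference_ids(self) -> list[str]:
        return list(self.rows.index)

    def native_to_reference(self, species: str) -> dict[str, str]:
        return dict(zip(self.rows[species], self.rows.index))


@dataclass
class AnchorAssignment:
    """Best cross-species match per group with margin and tie flag."""

    assignments: pd.DataFrame  # index: group_a; columns: best, r_best, margin, tie

    def best(self, group_a) -> object:
        return self.assignments.loc[group_a, "best"]


def harmonize_orthologs(
    tables: list[OrthologTable], reference_species: str
) -> OrthologMap:
    """Intersect strictly one-to-one filtered pairwise tables.

    Per table: every pair touching a gene that occurs in more than one row
    of that table is dropped.  A reference gene survives only if it has a
    one-to-one partner in every table.  Rows are ordered by reference gene
    id for determinism.
    """
    if not tables:
        raise PipelineError("no ortholog tables supplied")
    per_species: dict[str, dict[str, str]] = {}
    stage_counts: dict[str, tuple[int, int]] = {}
    for t in tables:
        if t.species_a == reference_species:
            other = t.species_b
            pairs = t.pairs
        elif t.species_b == reference_species:
            other = t.species_a
            pairs = [(b, a) for a, b in t.pairs]
        else:
            raise PipelineError(
                f"table {t.species_a}↔{t.species_b} does not involve the "
                f"reference species {reference_species!r}"
            )
        ref_counts = Counter(a for a, _ in pairs)
        oth_counts = Counter(b for _, b in pairs)
        kept = {
            a: b
            for a, b in pairs
            if ref_counts[a] == 1 and oth_counts[b] == 1
        }
        stage_counts[other] = (len(pairs), len(kept))
        per_species[other] = kept
    if reference_species in per_species:
        raise PipelineError("a table maps the reference species to itself")

    common = None
    for kept in per_species.values():
        keys = set(kept)
        common = keys if common is None else (common & keys)
    common = sorted(common or set())
    if not common:
        detail = ", ".join(
            f"{sp}: {n_in}→{n_kept}" for sp, (n_in, n_kept) in stage_counts.items()
        )
        raise PipelineError(
            f"no reference gene survives 1-1 harmonization ({detail})"
        )
    data = {reference_species: common}
    for species, kept in per_species.items():
        data[species] = [kept[r] for r in common]
    rows = pd.DataFrame(data, index=common)
    logger.info(
        "harmonize_orthologs: %d reference genes survive (%s)",
        len(common),
        "; ".join(f"{s}: {a}→{b}" for s, (a, b) in stage_counts.items()),
    )
    return OrthologMap(reference_species=reference_species, rows=rows)


def merge_on_orthologs(
    matrices: list[NormalizedMatrix], omap: OrthologMap
) -> dict[str, NormalizedMatrix]:
    """Re-index each species matrix to the reference gene order.

    A mapped gene absent from a species matrix becomes a zero row (counted
    in a warning); values of present genes are carried over bit-identically.
    Every output matrix has exactly ``len(omap.rows)`` rows.
    """
    out: dict[str, NormalizedMatrix] = {}
    ref_ids = omap.reference_ids
    for nm in matrices:
        if nm.species not in omap.rows.columns:
            raise PipelineError(f"species {nm.species!r} missing from ortholog map")
        native = omap.rows[nm.species]
        row_of = {g: i for i, g in enumerate(nm.gene_ids)}
        n_missing = 0
        dense_src = nm.values
        if sp.issparse(dense_src):
            dense_src = sp.csr_matrix(dense_src)
        new = np.zeros((len(ref_ids), nm.n_cells), dtype=float)
        for i, gid in enumerate(native):
            j = row_of.get(gid)
            if j is None:
                n_missing += 1
                continue
            row = dense_src[j]
            new[i, :] = (
                np.asarray(row.todense()).ravel() if sp.issparse(row) else row
            )
        if n_missing:
            logger.warning(
                "merge_on_orthologs(%s): %d mapped genes absent, zero-filled",
                nm.species,
                n_missing,
            )
        out[nm.species] = NormalizedMatrix(
            values=new,
            layer=nm.layer,
            species=nm.species,
            gene_ids=list(ref_ids),
            gene_symbols=list(ref_ids),
            cell_barcodes=list(nm.cell_barcodes),
            sample_of_cell=list(nm.sample_of_cell),
            scale_factor=nm.scale_factor,
            theta=nm.theta,
        )
    return out


def average_profiles(
    nm: NormalizedMatrix,
    groups: ClusterAssignment | np.ndarray | list,
    *,
    mean_of_expm1: bool = False,
) -> pd.DataFrame:
    """Per-group arithmetic mean expression: groups × genes.

    ``groups`` is a ClusterAssignment or any per-cell label sequence.
    ``mean_of_expm1`` averages de-logged expression instead of the lognorm
    values (exposed because either convention appears in practice).
    """
    labels = (
        groups.cluster_of_cell
        if isinstance(groups, ClusterAssignment)
        else np.asarray(groups)
    )
    if len(labels) != nm.n_cells:
        raise PipelineError("group labels do not match matrix cells")
    X = nm.dense()
    if mean_of_expm1:
        X = np.expm1(X)
    uniq = (
        sorted(set(labels.tolist()))
        if labels.dtype != object
        else sorted(set(labels))
    )
    rows = {}
    for g in uniq:
        mask = labels == g
        if not mask.any():
            raise PipelineError(f"empty group {g!r}")
        rows[g] = X[:, mask].mean(axis=1)
    return pd.DataFrame.from_dict(rows, orient="index", columns=nm.gene_ids)


def correlate_profiles(
    pa: pd.DataFrame,
    pb: pd.DataFrame,
    gene_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of every group pair over the gene axis.

    Both profile matrices must share an identical gene order.  Zero-
    variance profiles correlate 0 with everything (warned) rather than
    propagating NaN, keeping downstream anchoring total.
    """
    if list(pa.columns) != list(pb.columns):
        raise PipelineError("profile matrices have different gene orders")
    if gene_subset is not None:
        pa = pa[gene_subset]
        pb = pb[gene_subset]
    A = pa.to_numpy(dtype=float)
    B = pb.to_numpy(dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    zero_a = na == 0
    zero_b = nb == 0
    if zero_a.any() or zero_b.any():
        logger.warning(
            "correlate_profiles: %d zero-variance profiles, r set to 0",
            int(zero_a.sum() + zero_b.sum()),
        )
    na = np.where(zero_a, 1.0, na)
    nb = np.where(zero_b, 1.0, nb)
    R = (Ac / na[:, None]) @ (Bc / nb[:, None]).T
    R[zero_a, :] = 0.0
    R[:, zero_b] = 0.0
    R = np.clip(R, -1.0, 1.0)
    return pd.DataFrame(R, index=pa.index, columns=pb.index)


def anchor_groups(cm: pd.DataFrame, tie_epsilon: float = 1e-9) -> AnchorAssignment:
    """Argmax anchoring of every row group to its best column group.

    Ties break toward the lower column index with a warning; the tie flag
    is set when the top-two correlations differ by less than
    ``tie_epsilon``.
    """
    records = []
    for group_a, row in cm.iterrows():
        r = row.to_numpy(dtype=float)
        best = int(np.argmax(r))  # first occurrence = lower column index
        r_best = float(r[best])
        if len(r) > 1:
            rest = np.delete(r, best)
            r_second = float(rest.max())
        else:
            r_second = -np.inf
        margin = r_best - r_second
        tie = margin < tie_epsilon
        if tie and len(r) > 1:
            logger.warning(
                "anchor_groups: tie for %r, keeping lower column index", group_a
            )
        records.append(
            {
                "group_a": group_a,
                "best": cm.columns[best],
                "r_best": r_best,
                "margin": max(margin, 0.0) if np.isfinite(margin) else np.inf,
                "tie": bool(tie),
            }
        )
    df = pd.DataFrame(records).set_index("group_a")
    return AnchorAssignment(assignments=df)
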