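"""Cell/gene quality control and expression normalization.

Filtering follows the conventional order for droplet data: low-complexity
cells first (fewer detected genes than the floor), then high-mitochondrial
cells, then genes detected in too few of the surviving cells.

Two normalization layers are provided:

* ``lognorm`` — per-cell library-size scaling to ``scale_factor`` total
  counts followed by log1p.  Zero pattern is preserved; the layer is
  invariant to per-cell count scaling.
* ``pearson_residual`` — analytic Pearson residuals under a negative-
  binomial null with fixed inverse-dispersion ``theta``:
  ``(x − mu)/sqrt(mu + mu²/theta)`` with ``mu = total_c · gene_total_g /
  grand_total``, clipped to ``±sqrt(n_cells)`` by default.  This is the
  closed-form variance-stabilizing transform used for feature selection
  and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from crossortho.errors import ConfigError, EmptyAfterQCError, PipelineError
from crossortho.io_tenx import CountMatrix


@dataclass
class QCParams:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.20
    mito_gene_rule: str | Sequence[str] = "MT-"
    """Either a gene-symbol prefix (matched case-insensitively) or an
    explicit list of gene ids flagged as mitochondrial."""

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ConfigError("QC thresholds must be ≥ 0")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ConfigError("max_mito_fraction must be in [0,1]")


@dataclass
class QCReport:
    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    removed_low_gene_cells: int
    removed_high_mito_cells: int
    removed_rare_genes: int

    def __post_init__(self) -> None:
        assert self.cells_in - self.removed_low_gene_cells - self.removed_high_mito_cells == self.cells_out
        assert self.genes_in - self.removed_rare_genes == self.genes_out


@dataclass
class NormalizedMatrix:
    """A normalized gene×cell expression layer with carried-through metadata."""

    values: sp.spmatrix | np.ndarray
    layer: str  # "lognorm" | "pearson_residual"
    species: str
    gene_ids: list[str]
    gene_symbols: list[str]
    cell_barcodes: list[str]
    sample_of_cell: list[str] | None = None
    scale_factor: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.sample_of_cell is None:
            self.sample_of_cell = ["sample0"] * self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


def mito_gene_mask(m: CountMatrix, rule: str | Sequence[str]) -> np.ndarray:
    """Boolean mask of mitochondrial genes by symbol prefix or id list."""
    if isinstance(rule, str):
        prefix = rule.lower()
        return np.array(
            [s.lower().startswith(prefix) for s in m.gene_symbols], dtype=bool
        )
    wanted = set(rule)
    return np.array([g in wanted for g in m.gene_ids], dtype=bool)


def filter_counts(m: CountMatrix, p: QCParams) -> tuple[CountMatrix, QCReport]:
    """Apply the three QC passes in order and report attrition.

    (1) drop cells with detected genes < ``min_genes_per_cell``;
    (2) drop cells with mitochondrial count fraction > ``max_mito_fraction``;
    (3) drop genes detected in < ``min_cells_per_gene`` surviving cells.
    Cell and gene order is otherwise preserved.
    """
    counts = sp.csc_matrix(m.counts)
    n_genes_in, n_cells_in = counts.shape

    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_complexity = detected >= p.min_genes_per_cell
    n_low = int((~keep_complexity).sum())

    mito = mito_gene_mask(m, p.mito_gene_rule)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep_mito = mito_frac <= p.max_mito_fraction
    # low-gene rule applied first: a cell failing both is counted once
    n_mito_removed = int((keep_complexity & ~keep_mito).sum())
    keep_cells = keep_complexity & keep_mito
    if not keep_cells.any():
        raise EmptyAfterQCError(
            f"QC removed all {n_cells_in} cells "
            f"({n_low} low-complexity, {n_mito_removed} high-mito)"
        )

    sub = counts[:, keep_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= p.min_cells_per_gene
    n_rare = int((~keep_genes).sum())

    out = CountMatrix(
        species=m.species,
        counts=sub[keep_genes, :],
        gene_ids=[g for g, k in zip(m.gene_ids, keep_genes) if k],
        gene_symbols=[s for s, k in zip(m.gene_symbols, keep_genes) if k],
        cell_barcodes=[b for b, k in zip(m.cell_barcodes, keep_cells) if k],
        sample_of_cell=[s for s, k in zip(m.sample_of_cell, keep_cells) if k],
    )
    report = QCReport(
        cells_in=n_cells_in,
        cells_out=out.n_cells,
        genes_in=n_genes_in,
        genes_out=out.n_genes,
        removed_low_gene_cells=n_low,
        removed_high_mito_cells=n_mito_removed,
        removed_rare_genes=n_rare,
    )
    return out, report


def normalize_log(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Library-size lognorm: ``ln(1 + scale_factor · x / total_cell)``."""
    counts = sp.csc_matrix(m.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals <= 0).any():
        n_zero = int((totals <= 0).sum())
        raise PipelineError(
            f"{n_zero} cells have zero total counts; run QC filtering first"
        )
    scaled = counts.multiply(scale_factor / totals[None, :]).tocsc()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(scaled),
        layer="lognorm",
        species=m.species,
        gene_ids=list(m.gene_ids),
        gene_symbols=list(m.gene_symbols),
        cell_barcodes=list(m.cell_barcodes),
        sample_of_cell=list(m.sample_of_cell),
        scale_factor=scale_factor,
    )


def pearson_residuals(
    m: CountMatrix, theta: float = 100.0, clip: float | None = None
) -> NormalizedMatrix:
    """Analytic NB Pearson residuals with fixed inverse-dispersion.

    Genes with zero total count get an all-zero residual row.  ``clip``
    defaults to ``sqrt(n_cells)``.
    """
    if theta <= 0:
        raise ConfigError("theta must be > 0")
    X = np.asarray(sp.csr_matrix(m.counts).todense(), dtype=float)
    n_cells = X.shape[1]
    if clip is None:
        clip = np.sqrt(n_cells)
    cell_totals = X.sum(axis=0)
    gene_totals = X.sum(axis=1)
    grand = X.sum()
    if grand <= 0:
        return NormalizedMatrix(
            values=np.zeros_like(X),
            layer="pearson_residual",
            species=m.species,
            gene_ids=list(m.gene_ids),
            gene_symbols=list(m.gene_symbols),
            cell_barcodes=list(m.cell_barcodes),
            sample_of_cell=list(m.sample_of_cell),
            theta=theta,
        )
    mu = np.outer(gene_totals, cell_totals) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (X - mu) / np.sqrt(mu + mu * mu / theta)
    resid[gene_totals == 0, :] = 0.0
    np.clip(resid, -clip, clip, out=resid)
    return NormalizedMatrix(
        values=resid,
        layer="pearson_residual",
        species=m.species,
        gene_ids=list(m.gene_ids),
        gene_symbols=list(m.gene_symbols),
        cell_barcodes=list(m.cell_barcodes),
        sample_of_cell=list(m.sample_of_cell),
        theta=theta,
    )


def select_hvg(nm: NormalizedMatrix, n_top: int) -> np.ndarray:
    """Rank genes by per-gene variance of the layer, descending.

    Ties (and hence the all-constant case) break deterministically toward
    the lower gene index.
    """
    if n_top > nm.n_genes:
        raise ConfigError(f"n_top={n_top} exceeds {nm.n_genes} genes")
    if sp.issparse(nm.values):
        X = nm.values
        mean = np.asarray(X.mean(axis=1)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
        var = sq - mean**2
    else:
        var = np.asarray(nm.values).var(axis=1)
    order = np.lexsort((np.arange(len(var)), -var))
    return order[:n_top]
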