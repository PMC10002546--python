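"""Reading and writing 10x-style count triplets, ortholog tables and marker panels.

The on-disk contract mirrors what CellRanger emits for a single library: a
MatrixMarket coordinate-integer ``matrix.mtx`` holding gene×cell UMI counts,
a features/genes TSV naming the rows, and a barcodes TSV naming the columns.
Gzipped variants are accepted transparently by extension.  Internally all
indexing is 0-based; the MTX files stay 1-based per the MatrixMarket
standard.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from crossortho.errors import FormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Per-species sparse gene×cell UMI count matrix with metadata.

    ``gene_ids`` are the species-native stable identifiers used for all
    cross-species work; ``gene_symbols`` are display names used only for
    marker-panel matching (case-insensitive) and may repeat.
    """

    species: str
    counts: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    cell_barcodes: list[str]
    sample_of_cell: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.sample_of_cell is None:
            self.sample_of_cell = ["sample0"] * self.counts.shape[1]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"gene metadata length {len(self.gene_ids)}/{len(self.gene_symbols)} "
                f"does not match matrix row count {n_genes}"
            )
        if len(self.cell_barcodes) != n_cells:
            raise FormatError(
                f"{len(self.cell_barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(self.sample_of_cell) != n_cells:
            raise FormatError("sample_of_cell length does not match cell count")
        data = self.counts.data
        if data.size:
            if np.issubdtype(data.dtype, np.floating) and not np.allclose(
                data, np.round(data)
            ):
                raise FormatError("count matrix contains non-integer values")
            if data.min() < 0:
                raise FormatError("count matrix contains negative values")
        self.counts = self.counts.astype(np.int64)
        # barcodes must be unique within each sample
        seen: set[tuple[str, str]] = set()
        for bc, smp in zip(self.cell_barcodes, self.sample_of_cell):
            key = (smp, bc)
            if key in seen:
                raise FormatError(f"duplicate barcode {bc!r} within sample {smp!r}")
            seen.add(key)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class OrthologTable:
    """Pairwise gene correspondence between two species, possibly many-to-many."""

    species_a: str
    species_b: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        deduped: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for a, b in self.pairs:
            if not a or not b:
                raise FormatError("ortholog pair with empty gene id")
            if (a, b) not in seen:
                seen.add((a, b))
                deduped.append((str(a), str(b)))
        self.pairs = deduped


@dataclass
class MarkerPanelSet:
    """Named marker-gene panels at one annotation level.

    ``level`` is ``"somatic_germ"`` (germ vs somatic cell classes) or
    ``"germ_subtype"`` (SSC / progenitor / differentiating / late
    differentiating spermatogonia).
    """

    panels: dict[str, list[str]]
    level: str = "somatic_germ"

    def __post_init__(self) -> None:
        if not self.panels:
            raise FormatError("marker panel set is empty")
        for label, genes in self.panels.items():
            if not genes:
                raise FormatError(f"marker panel {label!r} is empty")
        if len(set(self.panels)) != len(self.panels):
            raise FormatError("duplicate panel labels")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(dir_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            cand = dir_path / name
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {list(stems)} (or .gz variants) found in {dir_path}"
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_mtx_triplet(dir_path: str | Path, species: str) -> CountMatrix:
    """Read a CellRanger-style MTX/features/barcodes triplet.

    Accepts both the three-column ``features.tsv`` dialect (id, symbol,
    feature type) and the older two-column ``genes.tsv`` dialect; in both
    cases gene ids and symbols are populated.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, ["matrix.mtx"])
    feat_path = _find_file(dir_path, ["features.tsv", "genes.tsv"])
    bc_path = _find_file(dir_path, ["barcodes.tsv"])

    with _open_maybe_gzip(mtx_path, "rt") as fh:
        text = fh.read()
    try:
        mat = scipy.io.mmread(io.StringIO(text))
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        raise FormatError(f"{feat_path} must have at least 2 columns (id, symbol)")
    gene_ids = feats[0].tolist()
    gene_symbols = feats[1].tolist()
    with _open_maybe_gzip(bc_path, "rt") as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if mat.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"MTX dimensions {mat.shape} do not match features "
            f"({len(gene_ids)}) × barcodes ({len(barcodes)})"
        )
    return CountMatrix(
        species=species,
        counts=mat,
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        cell_barcodes=barcodes,
    )


def write_mtx_triplet(m: CountMatrix, dir_path: str | Path) -> None:
    """Write a CountMatrix as an uncompressed MTX/features/barcodes triplet.

    Entry order in the MTX body is deterministic: column-major, then row
    (the CSC traversal order), so identical matrices produce byte-identical
    files.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    csc = sp.csc_matrix(m.counts)
    csc.sum_duplicates()
    scipy.io.mmwrite(
        str(dir_path / "matrix.mtx"), csc, field="integer", symmetry="general"
    )
    feats = pd.DataFrame(
        {
            0: m.gene_ids,
            1: m.gene_symbols,
            2: ["Gene Expression"] * m.n_genes,
        }
    )
    feats.to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for bc in m.cell_barcodes:
            fh.write(bc + "\n")


def read_ortholog_table(
    path: str | Path,
    species_a: str,
    species_b: str,
    *,
    has_header: bool = False,
) -> OrthologTable:
    """Read a two-column (Biomart-style) pairwise ortholog TSV.

    Rows with an empty field are skipped and tallied in a logged warning.
    Exact duplicate rows are dropped; otherwise file order is preserved.
    Many-to-many relations are allowed here — strict one-to-one filtering
    happens later in :mod:`crossortho.crosspecies`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=0 if has_header else None,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"ortholog table {path} is empty") from exc
    if df.shape[0] == 0:
        raise FormatError(f"ortholog table {path} is empty")
    if df.shape[1] < 2:
        raise FormatError(f"ortholog table {path} needs ≥2 columns")
    a_col = df.iloc[:, 0].astype(str)
    b_col = df.iloc[:, 1].astype(str)
    ok = (a_col.str.len() > 0) & (b_col.str.len() > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "read_ortholog_table(%s): skipped %d rows with empty fields",
            path,
            n_skipped,
        )
    pairs = list(zip(a_col[ok], b_col[ok]))
    if not pairs:
        raise FormatError(f"ortholog table {path} has no valid rows")
    return OrthologTable(species_a=species_a, species_b=species_b, pairs=pairs)


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in table.pairs:
            fh.write(f"{a}\t{b}\n")


def load_marker_panels(obj: dict | str | Path, level: str) -> MarkerPanelSet:
    """Build a MarkerPanelSet from a config mapping or a YAML file path."""
    if isinstance(obj, (str, Path)):
        import yaml

        with open(obj) as fh:
            obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise FormatError("marker panel definition must be a mapping")
    panels = {str(k): [str(g) for g in v] for k, v in obj.items()}
    return MarkerPanelSet(panels=panels, level=level)
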