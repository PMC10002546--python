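"""Synthetic multi-species scRNA-seq data with planted ground truth.

The generator emulates the statistical structure the cross-species analysis
assumes: several species share latent cell-type expression programs over a
common set of one-to-one orthologous genes, each species additionally
carries private (non-orthologous) genes, UMI counts are negative-binomial
with per-cell library-size variation, a small subset of genes is
mitochondrial (with a designated fraction of low-quality, mito-inflated
cells to exercise QC), and the pairwise ortholog tables are contaminated
with spurious many-to-many rows.

Planted signal comes in two flavours per cell type: *conserved* markers
(shared ortholog genes up-regulated by ``marker_fold`` in the target type
in every species) and *species-specific* markers (private genes
up-regulated in one species only).  Downstream modules should recover the
conserved markers and only those.

Generative model, per species, per cell ``c`` of type ``t``:

    counts[g, c] ~ NB(mean = lib_c * w[g, t] / sum_g w[g, t], theta)

with ``w[g, t] = baseline_g * marker_fold`` when ``g`` is a planted marker
of ``t`` active in this species, else ``baseline_g``; baselines are
log-normal, shared across species for ortholog genes and drawn
independently for private genes.  ``lib_c`` is log-normal.  The NB is
sampled as a gamma–Poisson mixture with variance ``mean + mean²/theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from crossortho.errors import ConfigError
from crossortho.io_tenx import (
    CountMatrix,
    MarkerPanelSet,
    OrthologTable,
    write_mtx_triplet,
    write_ortholog_table,
)

# canonical germ-subtype panel symbols used for the first four planted types,
# so the annotate module can be exercised with field-standard gene names
_CANONICAL_PANELS: list[tuple[str, list[str]]] = [
    ("SSC", ["FGFR3", "ID4", "PIWIL4", "TSPAN33", "UTF1"]),
    ("progenitor", ["NANOS3", "UPP1", "DUSP6", "ETV5", "ITGA6", "ZBTB16"]),
    ("differentiating", ["KIT", "DMRT1", "MKI67", "SOHLH1", "SOHLH2", "STRA8"]),
    ("late_differentiating", ["HORMAD1", "MEIOB", "SYCP2", "SYCP3"]),
]


@dataclass
class SimulationConfig:
    """Parameters of the multi-species generator.

    Defaults are the pipeline's reference study conditions: three species,
    five shared cell types, 2,000 ortholog genes plus 300 private genes per
    species, 900 cells per species, 2.5-fold planted markers (30 conserved
    and 20 species-specific per type) and NB inverse-dispersion 10.
    """

    n_species: int = 3
    species_names: tuple[str, ...] = ("human", "baboon", "rhesus")
    K: int = 5
    G_shared: int = 2000
    G_specific: int = 300
    cells_per_species: int = 900
    type_proportions: tuple[float, ...] | None = None
    base_expression: tuple[float, float] = (0.0, 1.0)
    marker_fold: float = 2.5
    markers_per_type: int = 30
    species_specific_markers_per_type: int = 20
    nb_theta: float = 10.0
    libsize_lognormal: tuple[float, float] = (math.log(5000.0), 0.35)
    mito_fraction_genes: float = 0.01
    high_mito_cell_fraction: float = 0.05
    mito_boost: float = 60.0
    ortholog_noise: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be ≥ 1")
        if len(self.species_names) < self.n_species:
            raise ConfigError("species_names shorter than n_species")
        self.species_names = tuple(self.species_names[: self.n_species])
        if self.type_proportions is None:
            self.type_proportions = tuple([1.0 / self.K] * self.K)
        props = np.asarray(self.type_proportions, dtype=float)
        if props.shape != (self.K,) or abs(props.sum() - 1.0) > 1e-9 or (props <= 0).any():
            raise ConfigError("type_proportions must be K positive values summing to 1")
        for name, val in [
            ("K", self.K),
            ("G_shared", self.G_shared),
            ("cells_per_species", self.cells_per_species),
            ("markers_per_type", self.markers_per_type),
        ]:
            if val <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.G_specific < 0 or self.ortholog_noise < 0:
            raise ConfigError("G_specific and ortholog_noise must be ≥ 0")
        if self.nb_theta <= 0 or self.marker_fold <= 0:
            raise ConfigError("nb_theta and marker_fold must be positive")
        n_mito = int(round(self.mito_fraction_genes * self.G_shared))
        if self.markers_per_type * self.K + n_mito > self.G_shared:
            raise ConfigError(
                "markers_per_type·K plus mitochondrial genes exceed G_shared"
            )
        if self.species_specific_markers_per_type * self.K > self.G_specific and (
            self.species_specific_markers_per_type > 0
        ):
            raise ConfigError(
                "species_specific_markers_per_type·K exceeds G_specific"
            )
        if not (0.0 <= self.mito_fraction_genes <= 1.0):
            raise ConfigError("mito_fraction_genes must be in [0,1]")
        if not (0.0 <= self.high_mito_cell_fraction <= 1.0):
            raise ConfigError("high_mito_cell_fraction must be in [0,1]")


@dataclass
class SyntheticGroundTruth:
    """Planted truth aligned with the emitted matrices."""

    true_type_of_cell: dict[str, np.ndarray]
    conserved_markers_of_type: dict[int, set[str]]  # reference gene ids
    species_specific_markers: dict[tuple[str, int], set[str]]  # native ids
    true_ortholog_map: dict[str, dict[str, str]]  # ref id -> species -> native id
    type_labels: dict[int, str] = field(default_factory=dict)
    panels: MarkerPanelSet | None = None
    mito_reference_ids: set[str] = field(default_factory=set)
    high_mito_cells: dict[str, np.ndarray] = field(default_factory=dict)


def _native_id(species: str, i: int) -> str:
    return f"{species.upper()[:3]}G{i:06d}"


def _specific_id(species: str, i: int) -> str:
    return f"{species.upper()[:3]}S{i:06d}"


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[CountMatrix], list[OrthologTable], SyntheticGroundTruth]:
    """Sample per-species count matrices, ortholog tables and ground truth.

    Fully reproducible from ``cfg.seed``: a single PRNG drives all draws in
    a fixed order, so two calls with the same config are byte-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    K = cfg.K
    Gs, Gp = cfg.G_shared, cfg.G_specific
    ref = cfg.species_names[0]

    # --- gene architecture over the shared ortholog space -----------------
    # marker blocks first, mitochondrial genes at the tail
    n_mito = int(round(cfg.mito_fraction_genes * Gs))
    conserved_idx = {
        t: np.arange(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type)
        for t in range(K)
    }
    mito_idx = np.arange(Gs - n_mito, Gs)

    mu_log, sigma_log = cfg.base_expression
    shared_baseline = rng.lognormal(mean=mu_log, sigma=sigma_log, size=Gs)

    # shared symbols; canonical germ-subtype panel symbols overlay the
    # lowest-baseline markers of the first four types (detection-based
    # panel scoring discriminates best on non-saturated genes)
    shared_symbols = [f"GS{i:05d}" for i in range(Gs)]
    for j, i in enumerate(mito_idx):
        shared_symbols[i] = f"MT-S{j:02d}"
    type_labels: dict[int, str] = {}
    panels: dict[str, list[str]] = {}
    for t in range(K):
        if t < len(_CANONICAL_PANELS):
            label, symbols = _CANONICAL_PANELS[t]
        else:
            label = f"type{t}"
            symbols = [f"T{t}M{j}" for j in range(5)]
        type_labels[t] = label
        block = conserved_idx[t]
        order = block[np.argsort(shared_baseline[block], kind="stable")]
        chosen = order[: min(len(symbols), len(block))]
        used = []
        for sym, gi in zip(symbols, chosen):
            shared_symbols[gi] = sym
            used.append(sym)
        panels[label] = used
    panel_set = MarkerPanelSet(panels=panels, level="germ_subtype")

    # --- per-species sampling --------------------------------------------
    props = np.asarray(cfg.type_proportions, dtype=float)
    lib_mu, lib_sigma = cfg.libsize_lognormal
    matrices: list[CountMatrix] = []
    truth_types: dict[str, np.ndarray] = {}
    species_markers: dict[tuple[str, int], set[str]] = {}
    high_mito: dict[str, np.ndarray] = {}

    for species in cfg.species_names:
        spec_baseline = (
            rng.lognormal(mean=mu_log, sigma=sigma_log, size=Gp) if Gp else np.empty(0)
        )
        baseline = np.concatenate([shared_baseline, spec_baseline])
        G = Gs + Gp

        # rate matrix gene × type for this species
        rates = np.tile(baseline[:, None], (1, K)).astype(float)
        for t in range(K):
            rates[conserved_idx[t], t] *= cfg.marker_fold
            if cfg.species_specific_markers_per_type and Gp:
                lo = t * cfg.species_specific_markers_per_type
                hi = lo + cfg.species_specific_markers_per_type
                spec_block = Gs + np.arange(lo, hi)
                rates[spec_block, t] *= cfg.marker_fold
                species_markers[(species, t)] = {
                    _specific_id(species, i - Gs) for i in spec_block
                }
            else:
                species_markers[(species, t)] = set()

        n_cells = cfg.cells_per_species
        cell_types = rng.choice(K, size=n_cells, p=props)
        libs = rng.lognormal(mean=lib_mu, sigma=lib_sigma, size=n_cells)
        n_high = int(round(cfg.high_mito_cell_fraction * n_cells))
        high_cells = rng.choice(n_cells, size=n_high, replace=False)
        is_high = np.zeros(n_cells, dtype=bool)
        is_high[high_cells] = True

        mean = np.empty((G, n_cells), dtype=float)
        for t in range(K):
            for flag in (False, True):
                mask = (cell_types == t) & (is_high == flag)
                if not mask.any():
                    continue
                w = rates[:, t].copy()
                if flag:
                    w[mito_idx] *= cfg.mito_boost
                p = w / w.sum()
                mean[:, mask] = p[:, None] * libs[mask][None, :]

        lam = rng.gamma(shape=cfg.nb_theta, scale=mean / cfg.nb_theta)
        counts = rng.poisson(lam)

        gene_ids = [_native_id(species, i) for i in range(Gs)] + [
            _specific_id(species, i) for i in range(Gp)
        ]
        gene_symbols = shared_symbols + [
            f"{species.upper()[:3]}SP{i:05d}" for i in range(Gp)
        ]
        barcodes = [f"{species}-{i:05d}" for i in range(n_cells)]
        half = n_cells // 2
        samples = ["rep1"] * half + ["rep2"] * (n_cells - half)
        matrices.append(
            CountMatrix(
                species=species,
                counts=sp.csr_matrix(counts),
                gene_ids=gene_ids,
                gene_symbols=gene_symbols,
                cell_barcodes=barcodes,
                sample_of_cell=samples,
            )
        )
        truth_types[species] = cell_types
        high_mito[species] = np.flatnonzero(is_high)

    # --- ortholog tables ---------------------------------------------------
    tables: list[OrthologTable] = []
    for species in cfg.species_names[1:]:
        pairs = [
            (_native_id(ref, i), _native_id(species, i)) for i in range(Gs)
        ]
        # spurious many-to-many contamination confined to private genes so
        # the planted one-to-one backbone is never silently deleted
        if cfg.ortholog_noise and Gp:
            a_idx = rng.integers(0, Gp, size=cfg.ortholog_noise)
            b_idx = rng.integers(0, Gp, size=cfg.ortholog_noise)
            noise = {
                (_specific_id(ref, int(a)), _specific_id(species, int(b)))
                for a, b in zip(a_idx, b_idx)
            }
            pairs.extend(sorted(noise))
        tables.append(
            OrthologTable(species_a=ref, species_b=species, pairs=pairs)
        )

    true_map = {
        _native_id(ref, i): {
            species: _native_id(species, i) for species in cfg.species_names
        }
        for i in range(Gs)
    }
    conserved = {
        t: {_native_id(ref, int(i)) for i in conserved_idx[t]} for t in range(K)
    }
    truth = SyntheticGroundTruth(
        true_type_of_cell=truth_types,
        conserved_markers_of_type=conserved,
        species_specific_markers=species_markers,
        true_ortholog_map=true_map,
        type_labels=type_labels,
        panels=panel_set,
        mito_reference_ids={_native_id(ref, int(i)) for i in mito_idx},
        high_mito_cells=high_mito,
    )
    return matrices, tables, truth


def write_dataset(
    matrices: list[CountMatrix],
    tables: list[OrthologTable],
    truth: SyntheticGroundTruth,
    dir_path: str | Path,
) -> None:
    """Write a generated dataset: one MTX triplet per species, ortholog
    TSVs, a ground-truth TSV (species, barcode, true_type) and, when
    present, the planted marker panels as YAML."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        write_mtx_triplet(m, dir_path / m.species)
    for t in tables:
        write_ortholog_table(
            t, dir_path / f"orthologs_{t.species_a}_{t.species_b}.tsv"
        )
    rows = []
    for m in matrices:
        types = truth.true_type_of_cell[m.species]
        for bc, tt in zip(m.cell_barcodes, types):
            rows.append((m.species, bc, int(tt)))
    pd.DataFrame(rows, columns=["species", "barcode", "true_type"]).to_csv(
        dir_path / "truth.tsv", sep="\t", index=False
    )
    marker_rows = [
        (int(t), gid)
        for t in sorted(truth.conserved_markers_of_type)
        for gid in sorted(truth.conserved_markers_of_type[t])
    ]
    pd.DataFrame(marker_rows, columns=["true_type", "reference_gene_id"]).to_csv(
        dir_path / "conserved_markers.tsv", sep="\t", index=False
    )
    if truth.panels is not None:
        import yaml

        with open(dir_path / "panels.yaml", "w") as fh:
            yaml.safe_dump(
                {k: list(v) for k, v in truth.panels.panels.items()},
                fh,
                sort_keys=True,
            )
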