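# Desk-scale demonstration config: three simulated species, four shared
# cell types, a few hundred cells.  Runs the full pipeline in ~30 s.
seed: 7
output_dir: crossortho_out
reference_species: human

simulation:
  n_species: 3
  species_names: [human, baboon, rhesus]
  K: 4
  G_shared: 400
  G_specific: 60
  cells_per_species: 240
  markers_per_type: 12
  species_specific_markers_per_type: 6
  marker_fold: 3.0
  nb_theta: 10.0
  ortholog_noise: 15

qc:
  min_genes_per_cell: 50
  min_cells_per_gene: 3
  max_mito_fraction: 0.20

cluster:
  n_pcs: 20
  k_neighbors: 15
  resolution: 0.5

de:
  min_pct: 0.10
  min_logfc: 0.25
  alpha: 0.05

n_hvg: 400
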