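grid_rows: 120
grid_cols: 120
cell_size: 1.0
classes:
  - {code: 1, proportion: 0.45}   # forest-like matrix
  - {code: 2, proportion: 0.35}   # pasture
  - {code: 3, proportion: 0.20}   # cropland
years: [1992, 2020]
ocean_fraction: 0.15
cluster_density: 0.5
seed: 42
operators:
  - {start_year: 1993, end_year: 2020, kind: contract, source: 1, target: 2, rate: 12}
  - {start_year: 1993, end_year: 2020, kind: expand, source: 3, rate: 8}
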