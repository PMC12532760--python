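scenario: scenario.yaml
extents_km: [10, 20, 40]
change_years: [1992, 2020]
seed: 42
out_dir: example_out
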