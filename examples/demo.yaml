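# Demo run: 64x64 synthetic world, full pipeline.
out_dir: scratch/demo-run
seed: 7
simulate:
  grid_shape: [64, 64]
  n_countries: 6
  n_bcus: 8
habitat_agg: mean
clip_quantile: 0.9999
country_aggregation: mean_of_portions
outlier_rule: iqr
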