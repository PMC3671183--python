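# Full-pipeline example: three-probe synthetic cohort + qPCR stage.
# Run:  episcan run --config configs/example.yaml --out report.json
seed: 1
outdir: episcan_out
stages: [simulate, scan, average, window_stats, qpcr]

epithelium:
  preset: olfactory_cohort   # Gb1-like / Gg13-like / GAP43-like, designed ratio 2.0
  small: true           # trimmed canvas, full-size epithelium geometry

cohort:
  n_animals: 3
  images_per_animal: 2
  scans_per_image: 2    # 4 scans per animal

scan:
  length_um: auto       # synthetic apical edge is image row 0
  step_px: 1

averaging:
  n_points_animal: 500
  n_points_group: 100

window:
  x1: 0.63
  x2: 0.93

comparisons:
  - [Gb1-like, Gg13-like]
ks_mode: pointwise_values

qpcr:
  reference_gene: Gapdh
  mode: delta_ct
  anova: true
  design:
    genes: [Gapdh, Gb1, Gg8, Gg13]
    true_rel_expression: {Gb1: 1.3, Gg8: 0.5, Gg13: 9.3}
    n_biological: 3
    n_technical: 3
    ct_noise_sd: 0.2
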