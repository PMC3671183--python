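# episcan

Depth-resolved quantification of RNA in situ hybridization (RISH) signal in
layered epithelia, with a companion qPCR relative-quantification stage.

## The problem

Colorimetric RISH shows *where* in a layered epithelium (for example the
mouse main olfactory epithelium, with its sustentacular, mature-neuron,
immature-neuron and basal-cell strata) a transcript is expressed, but a
picture alone cannot say how two probes' depth distributions differ.
`episcan` turns micrographs into comparable depth profiles:

1. **Invert** the brightfield image so stain = high intensity.
2. **Scan**: sample intensity along straight segments anchored on a traced
   basal lamina and oriented perpendicular to its local tangent, running
   from the apical side down to the lamina (bilinear interpolation, 1-px
   steps by default).
3. **Normalize** each scan: depth `x` to the scan length (`x = 0` apical,
   `x = 1` at the basal lamina) and intensity `y` to the profile peak.
4. **Hierarchical averaging**: scans → animal curve on a 500-point grid
   (linear interpolation, then renormalized to peak 1) → group curve on a
   100-point grid with per-point SEM over animals.
5. **Window statistics**: the area integral `∫ y dx` of each probe's group
   curve over a basal marker window `[x1, x2]` (default `0.63–0.93`, the
   band of an immature-neuron marker such as GAP43, or derived from a
   marker curve by half-max crossings), pairwise integral ratios, and a
   two-sample Kolmogorov–Smirnov comparison of two probes' curve values
   restricted to the window (`D = sup |ECDF₁ − ECDF₂|`, asymptotic p at
   effective `n = n₁n₂/(n₁+n₂)`; a `density_cdf` mode treating curves as
   densities over depth is also provided).
6. **qPCR**: comparative-Ct quantification of Ct tables —
   `ΔCt = Ct(gene) − Ct(reference)`, `fold = 2^−ΔCt` per sample then
   averaged (optionally `2^−ΔΔCt` against a calibrator group) — with
   one-way ANOVA and Tukey HSD across genes.

Because such studies rarely ship raw images, the package includes a seeded
synthetic-data generator (`episcan.synthetic`) producing ground-truth
epithelium images — sinusoidal basal lamina, depth-stratified layers,
continuous fill or Poisson-seeded cell-body blobs, Gaussian noise — and
designed Ct tables, so every stage is testable end to end.

## Worked example

The shipped config simulates a three-probe cohort (3 animals × 2 images ×
2 scans per probe): `Gb1-like` fills the whole neuron layer, `Gg13-like`
only its upper portion, `GAP43-like` exactly the marker window, with the
upper/lower boundary placed so the true windowed-integral ratio
Gb1:Gg13 is 2.0.

```sh
episcan run --config configs/example.yaml --out report.json
```

prints (abridged; seed 1):

```text
"integrals": { "GAP43-like": 0.2558, "Gb1-like": 0.2502, "Gg13-like": 0.1290 }
"ratios":    [ { "probe_num": "Gb1-like", "probe_den": "Gg13-like", "ratio": 1.939 }, ... ]
"ks":        [ { "D": 0.60, "p_value": 4.08e-05, "n1": 30, "n2": 30,
                 "mode": "pointwise_values" } ]
"folds":     { "Gb1/MOE": 1.344, "Gg13/MOE": 9.956, "Gg8/MOE": 0.498, "Gapdh/MOE": 1.0 }
"anova":     { "F": 133.5, "p_value": 1.06e-05, ... }
```

Reading this: the full-layer probe carries about twice the windowed signal
of the restricted probe (1.94 recovered vs 2.0 designed), the two depth
distributions differ significantly within the window (KS `p < 0.01`), and
the qPCR stage recovers the designed fold changes (9.3, 1.3, 0.5 relative
to the Gapdh reference) within noise. Subcommands `simulate`, `scan`,
`average`, `window-stats` and `qpcr` run individual stages on the CSV/TIFF
interchange files; the same functionality is available as a library
(`episcan.simulate_cohort_curves`, `episcan.area_integral`, …).

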