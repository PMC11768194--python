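# breadtex

Analysis toolkit for composite-flour bread studies: crumb-slice pore
segmentation and air-space counting, CIELAB colour-difference computation
with perceptual classification, Chopin+-style MixoLab torque-curve
parameter extraction (C1–C5, slopes, stability, gelling mid-point), and
the group-comparison statistics (one-way ANOVA, Tukey HSD, compact letter
displays) used to build lettered result tables.  A synthetic-data module
generates ground-truthed crumb images, parametric torque curves and
replicate colour readings so every stage is testable without instrument
data.

## Modules

| module                 | what it does |
|------------------------|--------------|
| `breadtex.synthetic`   | seeded generators: Boolean pore scenes, anchor-interpolated torque curves, Gaussian colour replicates |
| `breadtex.crumb`       | slice masking (alpha / white-threshold), Otsu or 2-means pore segmentation, connected regions, size-class statistics, area-coded colourmap rendering |
| `breadtex.colorimetry` | replicate averaging, ΔE (CIE76 by default, CIEDE2000 optional), five-band perceptual classification, substitution-level trend fits |
| `breadtex.mixolab`     | torque/temperature phase detection, smoothing envelopes, landmark extraction (T_hydr, T1, C1, amplitude, stability, slope-α/β, C2, C3, T3, gelling mid-point, C4, C5) |
| `breadtex.groupstats`  | one-way ANOVA, Tukey HSD (Tukey–Kramer when unbalanced), insert-and-absorb compact letter display |
| `breadtex.pipeline` / `breadtex.cli` | config-driven batch runs and the `breadtex` command line |

## CLI

```sh
breadtex demo --seed 1 --out fixtures        # write a synthetic fixture set
breadtex run --config fixtures/config.yaml   # full pipeline -> report.json, lettered tables, colourmaps

breadtex simulate-crumb  --seed 1 --n-pores 40 --out scene/
breadtex analyze-crumb   scene/crumb.png --out pores.json
breadtex simulate-curve  --params params.yaml --out curve.csv
breadtex extract-mixolab curve.csv --out mixolab.json
breadtex simulate-colors --means means.yaml --out colors.csv
breadtex color-diff      colors.csv --reference control
breadtex compare-groups  table.csv --value-col value
```

Curves travel as CSV (`time_min,torque_nm,temp_c`), colour readings as
CSV (`group,replicate,L,a,b`), images as PNG/JPEG/TIFF in and PNG out.
The pipeline report is bit-identical across reruns with the same config
and inputs (only the run log carries a timestamp).

## Conventions worth knowing

- ΔE bands are half-open — `[0,1) [1,2) [2,3.5) [3.5,5) [5,∞)`; a value
  sitting exactly on a boundary belongs to the upper band.
- Stability is the time the smoothed torque stays within 11% below C1
  (configurable), measured as the contiguous band around T1; on strong
  doughs it extends past the isothermal mixing phase, as on the
  instrument.
- T_hydr is defined as the first crossing of 50% of C1 (configurable
  fraction) — a convention, echoed in outputs.
- Size-class boundaries (default small < 100 px², medium < 1000 px²) are
  reporting conventions carried in every output, not physical constants.
- The default temperature schedule is 8 min at 30 °C, 4 °C/min ramp to
  90 °C, 7 min hold, 4 °C/min cooling to 50 °C, 45 min total; every
  segment is configurable via `ChopinProtocol`.

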