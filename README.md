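# cocmatrix

Quantitative analysis toolkit for cumulus–oocyte-complex (COC) matrix
biology. It implements, as tested and reusable Python, the full analysis
stack for:

- **Solid-state-nanopore hyaluronan sizing** — translocation event
  detection in ionic-current traces (5σ threshold on a 5 kHz zero-phase
  analysis filter, 25 µs – 2.5 ms duration window), event-area →
  molecular-weight mapping through a monotone log–log calibration curve,
  and polydispersity summaries (mass-weighted average MW, fraction below
  300 / 50 kDa, histograms, ≥500-event QC).
- **Particle-exclusion assay (PEA)** — percent porosity (infiltrated area
  over whole-COC area) and nanoparticle mean fluorescent intensity per
  pixel from multi-channel COC images.
- **HABP intensity quantification** — equal-sized cellular vs
  intercellular ROIs (nine per COC across z-planes), category values as
  means of per-ROI means.
- **Cumulus-expansion morphokinetics** — pre/post area and thickness
  deltas (difference-between-differences inputs), hourly edge-distance
  series to 1 h / 4 h velocity profiles in µm/min with peak-window
  labelling.
- **RT² array ΔΔCt analysis** — five-housekeeping-gene normalisation,
  Ct = 35 floor, per-replicate 2^−ΔΔCt, replicate averaging, ±1.5
  fold-change regulation calls and log2 transform.
- **Study statistics** — Shapiro–Wilk-gated t / Mann–Whitney selection,
  cluster-aware nested t-test, Box–Cox transform with λ = −0.4242,
  one-way ANOVA with Tukey HSD and compact letter display, Fisher /
  chi-square categorical tests, and 4PL ELISA standard-curve fitting
  with inversion.

A first-class `synthetic` subpackage generates every input the pipeline
consumes (current traces, COC image stacks, expansion time courses, Ct
tables) with ground-truth sidecars, so every stage is testable end to
end without external data.

## Layout

```
src/cocmatrix/
  synthetic/    input generators + ground-truth sidecars
  nanopore.py   event detection, calibration, polydispersity
  imaging.py    COC segmentation, PEA porosity, HABP ROI intensities
  kinetics.py   expansion deltas and velocity profiles
  qpcr.py       ΔΔCt fold changes, floors, regulation calls
  stats.py      the statistical procedures above
  io.py         trace/TIFF/CSV/JSON formats
  cli.py        command-line interface
```

## Command line

One entry point, `cocmatrix`, with a group per stage:

```bash
# generate a seeded trace + truth sidecar, then size it
cocmatrix synth trace --seed 3 --config trace.json --out run/
cocmatrix nanopore size run/trace.f32 run/calibration.csv \
    --threshold-sigma 5 --min-dur 25e-6 --max-dur 2.5e-3 \
    --lowpass 5000 --min-events 500 --out run/sized/

# synthetic COC image -> porosity, HABP intensities
cocmatrix synth image --seed 1 --out img/
cocmatrix imagequant pea img/coc.tiff --threshold otsu --out pea.csv
cocmatrix imagequant habp img/coc.tiff --out habp.csv

# expansion kinetics and group comparison
cocmatrix synth timelapse --seed 1 --out tl/
cocmatrix kinetics profile tl/distances.csv --out profiles.csv
cocmatrix kinetics compare records.csv --metric area --nested --out cmp.json

# ddCt fold changes
cocmatrix synth cttable --seed 1 --out ct/
cocmatrix qpcr fc ct/ct.csv ct/samples.csv --floor 35 --up 1.5 --out fc.csv

# statistics
cocmatrix stats compare tidy.csv --nested --boxcox-lambda -0.4242 --out res.json
cocmatrix stats elisa-4pl standards.csv samples.csv --out conc.csv
```

Traces travel as raw little-endian float32 samples plus a JSON metadata
sidecar (or single-column CSV); images as multi-page TIFF plus JSON
(pixel size, channel names); tables as headered CSV; reports as JSON.

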