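# hsafm_cme

Quantification pipeline for hybrid high-speed AFM / confocal imaging of
clathrin-mediated endocytosis (CME).

Tip-scanning high-speed AFM combined with a confocal scanner images the
apical plasma membrane of a living cell while fluorescence channels
report protein assembly, so a clathrin-coated pit (CCP) can be followed
through its whole life: invagination, growth, and one of several closing
motions — *capping* (an adjacent actin-driven swelling covers the pit),
*two-step* (the aperture shrinks to a ~120 nm plateau before vanishing)
or *re-opening* (a closed pit reappears nearby). This package implements
the complete measurement chain for such data, and a physics-aware
synthetic-data generator that stands in for the (non-distributable)
live-cell movies, so every operator is validated by parameter recovery
against known ground truth.

The chain: probe-origin co-registration of the AFM and optical frames →
per-frame pit detection and greedy tracking with gap closing →
section-profile morphometry (aperture diameter between baseline edge
points, swelling height above the basal levels, tip-curvature correction
d → d − 2R, morphological-filter pit area) → phase segmentation of the
clathrin trace (stable phase = earliest run of > 4 frames with smoothed
slope in [−0.05, +0.1]/frame) → protein timing against the AFM anchors
(invagination start and pit closure, both t = 0 conventions) →
closing-motion classification → drift-corrected diffusion (drift = the
ensemble-mean pit displacement, since random diffusers average to zero;
MSD = 4Dt over the first lags).

## Layout

- `src/hsafm_cme/` — the library: `config` (study-condition defaults and
  perturbation presets), `events`/`traces`/`render`/`generate` (the
  synthetic-data generator), `movio`/`registration` (TIFF + sidecar IO,
  AFM↔optical transforms), `detection`/`tracking`, `morphometry`,
  `lifecycle` (phase segmentation, timing), `motions` (closing-motion
  classifier), `diffusion`, `pipeline` (simulate → analyze → evaluate),
  `studies` (the reference experiments), `cli`.
- `analysis/` — numbered drivers that run each study and write tables
  under `results/`.
- `docs/methods.md` — the model, the measurement operators, and what the
  synthetic validation does and does not show.

## Worked example

```sh
python analysis/05_diffusion_and_drift.py
```

prints

```
drift null: |mean net displacement| = 520 nm over 2000 tracks (per-axis SE 534 nm; consistent with 0)
CCP      D = 7.16e-09 cm^2/s (configured 7.3e-09, -1.9%)
caveola  D = 2.06e-09 cm^2/s (configured 2.1e-09, -1.9%)
```

The first line is the drift-estimator null: for 2,000 drift-free
Brownian pits the ensemble net displacement is statistically zero (the
observed 520 nm magnitude is within one SE of the 2-D sampling
distribution), which is what licenses using the pit-ensemble mean as a
drift estimate. The next lines recover both class diffusion coefficients
from drift-corrupted (20 nm/frame), then drift-corrected, simulated
tracks — CCPs diffuse ~3.5× faster than caveolae, the basis for
distinguishing the two invagination types kinetically.

```sh
python analysis/06_morphometry_recovery.py
```

prints

```
swelling: 363 nm wide, 37.3 nm high (n=49; generator draws 378/38 nm)
two-step plateau median: 123 nm (n=49 events; generator plateau 120 nm)
```

i.e. the section-profile operators recover the capping-swelling geometry
and the small-aperture plateau to within a pixel (18.75 nm) on rendered,
noisy movies. `analysis/01…04` simulate full-field reference bundles,
run the end-to-end analysis with ground-truth scoring, and tabulate
protein timing and closing-motion frequencies per perturbation preset.

A thin CLI wraps the same pipeline:

```sh
hsafm-cme simulate --preset untreated --seed 1 --outdir sim/
hsafm-cme evaluate --indir sim/ --outdir out/
```

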