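# Methods

`hsafm_cme` quantifies clathrin-mediated endocytosis (CME) from hybrid
high-speed AFM (HS-AFM) / confocal (CLSM) time-lapse movies: AFM height
maps resolve the membrane invagination itself (aperture, depth, swelling
geometry, open/closed state) while one or two fluorescence channels
report protein assembly (clathrin, epsin, dynamin, actin, caveolin).
Because no real movie data are distributable, every quantitative claim
in this package is exercised against a synthetic-data generator whose
defaults encode the study conditions; the generator is first-class,
tested code, and its scripts double as ground truth for scoring the
analysis chain.

## Imaging model (the generator)

**Geometry.** The AFM scan covers 6.0 × 4.5 µm² at 18.75 nm/pixel
(320 × 240), one frame every 10 s. Pixel (r, c) is centred at
((c + 0.5)·px, (r + 0.5)·px) in scan-local nm; the registration module
maps this onto a probe-centred common frame (+y up) whose origin is the
parked probe's autofluorescence spot, with the scan rectangle at the
corners (−3, 2.25) … (3, −2.25) µm.

**Pits.** An open pit of aperture a (diameter) is a radial depression
z(r) = −depth · cos(π r / (2·a/2)) for r < a/2: the profile crosses the
baseline exactly at the aperture radius with a finite rim slope, so a
noiseless section profile recovers the scripted aperture. A smooth
tangential (squared-cosine) bowl was rejected because its zero rim slope
makes any edge-tolerance diameter measurement systematically low. Pit
depth is 30 nm by default — the depth of these invaginations is not an
observable we can anchor, so it is a free parameter chosen once; all
detector thresholds (10 nm minimum depth) are consistent with it.

**Sizes and kinetics.** CCP apertures are uniform on 150–400 nm
(as-measured AFM values; a tip-curvature subtraction of 2 × 10 nm maps
them onto 130–380 nm), caveolae 80–120 nm and open for the whole movie.
CCP lifetimes are drawn as 40 s + LogNormal(mean 41 s, SD 55 s) rejected
above 330 s, reproducing the observed mean 81 s / SD 55 s / range
40–330 s; a normal truncated to those bounds cannot reach that mean/SD
combination (the lower bound sits only 0.75 SD below the mean), which is
why the family is lognormal. The drawn lifetime always spans birth →
final closure; a re-opening event partitions it into first open period,
closed gap (10–70 s) and second open period, and re-opens at the closure
position plus a displacement drawn uniform on 13–113 nm (the quoted
displacement is the total closed-to-reopened offset, so the trajectory
does not diffuse freely through the gap).

**Closing motions.** Labels are drawn with marginals capping 54.9%,
two-step 20%, re-opening 10% (untreated); capping and re-opening are
mutually exclusive (they are inversely related in the data), two-step is
independent. Capping renders a positive bump (diameter N(378, 62) nm,
height N(38, 10) nm) that grows adjacent to the pit — offset
0.9 × (r_pit + r_swelling) along a random direction — and covers the pit
centre from the closure frame onward; keeping it adjacent until closure
matters, because a gradually encroaching bump narrows the apparent
aperture and masquerades as a two-step plateau. Two-step sets the final
1–4 open frames (10–40 s) to the 120 nm plateau diameter. Perturbation
presets (cytoB, CK666, jasp, siDNM2) re-weight these marginals and the
lifetime/phase distributions; only capping/re-open percentages are
anchored to reported values, the two-step weights are package choices.

**Mobility.** Per-class diffusion coefficients default to
D_CCP = 7.3 × 10⁻⁹ and D_caveola = 2.1 × 10⁻⁹ cm²/s, and all
trajectory-level analyses (drift null, MSD recovery) use them directly.
Those values imply an RMS step of ~3.8 µm per 10-s frame — larger than
the scan field — so a pit at that mobility cannot be rendered and
tracked in-field for its lifetime. Rendered-movie studies therefore use
an in-field mobility of 3 × 10⁻¹² cm²/s (~110 nm step per frame,
consistent with the 250 nm linking radius); `D_IN_FIELD_CM2_S` marks
this as an explicit package choice. This tension between the quoted
mobility and the quoted geometry is inherited from the source data and
is not reconciled here.

**Fluorescence.** Spots are 2-D Gaussians (σ = 106 nm ≈ 250 nm FWHM
confocal) on an 83 nm optical grid, with Poisson photon noise on a
20-photon/px background, Gaussian read noise (σ = 2), and an integrated
intensity of 1000 photons at trace maximum. Traces are piecewise-linear:
a nucleation step to 0.18 at appearance, a fast climb to 0.8 within 2–4
frames, a slow plateau, near-symmetric shoulders (0.85 / 0.8 at
±2.5 frames) around the maximum, and a terminal step at disappearance.
Channel anchors are drawn per event: appearance 47±9 (epsin), 34±13
(clathrin), 25±12 s (dynamin) before invagination and 59±18 s before
closure (actin); peaks 14±5 s before (epsin), 3±7 s after (clathrin),
at (dynamin) and 2.5±7 s after closure (actin); disappearance 13±5,
39±13, 38±9 s after closure. Actin's disappearance is not reported and
defaults to 30±10 s. During a re-opening gap the clathrin trace dips to
a retained fraction drawn N(0.39, 0.18) clipped to [0.14, 0.70]. The two
scanners are unsynchronized: each movie draws one AFM↔CLSM lag uniform
on [0, 10) s, applied to the fluorescence sampling comb and never
corrected in analysis (matching instrument practice).

**Artifacts.** Tip skips replace 1–2 consecutive scan lines (19–37 nm at
the default pixel) with the previous line plus an offset, at 0.01/frame;
amplitude steps rescale texture contrast at 0.002/frame. All injections
are logged, and detection masks logged rows out. Tip convolution is a
grayscale dilation with a spherical-cap structure function; at the
default 10 nm tip radius the footprint is below one pixel, so the
imaging broadening is negligible while the 2R = 20 nm diameter
correction is still applied on the reporting side — the package deliber-
ately implements both conventions without reconciling their signs.

## Measurement operators

**Detection.** A pit is a connected region ≥ 10 nm below a local
baseline (median in a 750 nm window, computed on a 4× decimated grid);
merged regions are split by watershed at depth maxima ≥ 150 nm apart;
detections smaller than 60 nm equivalent diameter are dropped, and a
track must contain two consecutive frames to be confirmed.

**Section-profile morphometry.** Diameter: bilinear line profile through
the centroid; baseline = mean of the two flank medians (outer 25% per
side); edge per side found by walking outward from the minimum to the
first sample above `baseline − tol`, with
tol = max(1 nm, 3 × flank MAD σ, 15% of pit depth) capped at half the
depth, then projecting along the steepest adjacent wall chord to the
baseline itself. The deep, noise-adaptive threshold stops correlated
membrane roughness from dragging the edge outward (the naive 1 nm
tolerance is biased +67 nm at σ_z = 2 nm), and the wall projection
removes the inward bias the deep threshold would otherwise introduce;
net bias is under one pixel across 120–400 nm apertures at all section
angles. Height: profile maximum minus the mean of the two basal-level
medians. Area: 3×3 median → black top-hat (disk, 20 px) → opening and
closing (disk, 6 px) → half-max threshold within the ROI, pixel count ×
pixel area; the black variant is used because pits are depressions.

**Tracking.** Greedy nearest-neighbour frame-to-frame linking within
250 nm (adequate at these pit densities — a documented simplification
versus global assignment), followed by gap closing across ≤ 7 missing
frames within 140 nm. The 140 nm gate is the 113 nm maximum re-open
displacement plus localization error (~15–20 nm). The gap-closing pass
also re-links zero-gap splits within 350 nm, recovering the ~1% of
Brownian steps that exceed the linking radius. Identity: marker channel
colocalized within 150 nm in ≥ 50% of open frames (ties broken by
intensity), size prior as fallback (≤120 nm caveola-like, ≥150 nm
CCP-like). Lifetimes run from first detection to the first
detection-free frame after the last open frame; tracks alive at either
movie edge are censored. Formation frequency = newly born tracks /
(area × duration) in events·µm⁻²·min⁻¹.

**Phase segmentation.** On the max-normalised trace, smoothed with a
3-frame centered window (shrinking at the edges; that choice is ours),
per-frame slope by central differences: the stable phase is the earliest
run of ≥ 5 consecutive frames with slope in [−0.05, +0.1] per frame
("more than 4 frames" read strictly); growing/closing are the periods
before/after within the signal interval, delimited on the smoothed trace
at max(0.02, 3σ_noise/max). With no qualifying run the stable phase is
empty and the split is the smoothed argmax. Phases are *defined* by this
criterion, so the generator's ground-truth boundaries are the criterion
applied to the noise-free trace; a generative truth independent of the
criterion cannot exist, because a slow rise within the slope band is
stable by definition regardless of what produced it.

**Trace extraction.** Spot amplitudes are estimated by a sub-pixel
Gaussian matched filter after local-median background subtraction.
Inside the track the filter follows the (sub-pixel accurate,
crowding-immune) AFM detections, interpolated through gaps; before
birth and after closure it follows the spot with a per-frame refinement
chain (step ≤ 2.5 px, total excursion ≤ 6 px) so early assembly and
post-closure residence are captured without locking onto neighbours.

**Closing-motion classification.** Capping ⇔ a covering swelling:
a positive structure ≥ 20 nm high and ≥ 150 nm wide within 1.5 × the
last pit diameter (floored at 250 nm — the pit keeps diffusing between
its last detection and the swelling peak), whose footprint overlaps the
former pit centre at/after closure; its baseline uses a 1500 nm window
so a ~400 nm swelling cannot lift its own reference. Two-step ⇔ a
terminal run of frames with raw diameter in [60, 150) nm, preceded by
≥ 2 frames ≥ 140 nm whose median exceeds the plateau median by ≥ 25 nm
(a genuine step, not a measurement dip). Re-opening ⇔ a bridged gap of
1–7 frames with displacement ≤ 140 nm; the clathrin retention fraction
is the trace minimum in the gap over the trace maximum. Plain is the
residual. All aperture bands operate on raw (not tip-corrected)
diameters, since the quoted 150–400 / ~120 / 80–120 nm values are
as-measured.

**Drift and diffusion.** Stage drift is the per-frame-pair mean
displacement of all tracked pits, accumulated (random diffusers average
to zero, so the ensemble mean is the drift); the classic first-vs-last
estimate is kept as a compatibility mode. Tracks are drift-corrected,
time-averaged MSDs pooled pair-weighted per lag, and MSD = 4Dt fitted
with zero intercept over the first 4 lags (counts ≥ 10); tracks with
< 5 detections are excluded; a negative slope flags D = 0. The
nm²/s → cm²/s conversion is exact (1 cm² = 10¹⁴ nm²).

## What the tests show (and what they do not)

Recovery is measured against the generator, which emulates imaging
physics (PSF, shot/read noise, membrane roughness, tip skips, scan lag,
Brownian motion, drift) but idealises biology: pits are radially
symmetric, traces piecewise-linear, labels drawn independently, and the
membrane background is stationary Gaussian roughness without cortical
cytoskeleton texture, ruffles or neighbouring organelles. Passing tests
demonstrate that the measurement chain is unbiased and robust under
those conditions; they cannot certify the detector thresholds against
real membranes, where pit identification is in practice partly manual. Known quantitative limits, all reproduced deliberately rather
than hidden: fluorescence peak and disappearance times carry a ~−5 s
half-frame sampling bias plus the (uncorrected, mean ~5 s) AFM↔CLSM
lag; weak swellings near the 20 nm threshold are preferentially missed,
biasing mean measured swelling height up by ~1–2 nm; two pits closer
than the linking radius can swap identities (~1 event per few hundred).

## Problem sizes

Default study sizes: 2,000 trajectories for the drift null; 200
trajectories × 30 frames per class for diffusion; 50 single-event
96 × 96 px movies each for swelling and plateau morphometry; 300 events
in twenty 15-event full-field movies for the motion mixture; 200 events
for lifetime recovery. These sizes give sampling errors comfortably
inside the assertion tolerances (e.g. binomial SE ≈ 2.9 points on the
capping percentage at n = 300) while keeping any single study under a
few minutes on one core.
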