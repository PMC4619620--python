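# Methods

`calcytox` is a mechanistic, fully seeded model of the calcein-AM release
cytotoxicity assay and of its image-cytometry counterpart, built so that the
two percent-specific-lysis readouts can be compared under known ground truth.
This note records the model, its assumptions, the defaults and why they were
chosen, and what the synthetic data can and cannot say about real assays.

## Assay model

Target tumor cells are loaded with calcein; NK effector cells kill a fraction
of them over a 4-hour co-incubation; readouts are taken at the endpoint.

**Loading.** Per-cell calcein load is lognormal with mean `load_mean`
(100 AU) and coefficient of variation `load_cv` (0.25). A lognormal is
strictly positive and right-skewed, consistent with the divergent loading
observed across tumor lines, and is fully determined by the two parameters.
`load_cv = 0` degenerates to equal loading.

**Killing.** Each target in a test well dies independently with probability
`kill_frac_by_et[E:T]` — a single end-of-assay Bernoulli event. Both readouts
are endpoint measurements, so within-assay kinetics are deliberately not
modeled. Defaults: 0.9 / 0.6 / 0.35 at E:T 2:1 / 1:1 / 0.5:1. E:T ratios not
present in the map are rejected rather than interpolated, so configuration
mistakes surface immediately.

**Death modes.** A killed cell dies apoptotically with probability
`apoptotic_frac`, else necrosis-like:

* *Necrosis-like*: membrane rupture releases the calcein to the supernatant
  except for a retained fraction `necrotic_retention` (default 0.1 — a
  "minute quantity" of entrapped dye remains in the remnant).
* *Apoptotic*: the cell fragments into `bodies_per_cell` apoptotic bodies
  that jointly retain `apoptotic_retention` of the calcein (default 1.0 —
  apoptotic bodies retain the full load for the assay duration), split
  across bodies by a symmetric uniform Dirichlet draw.

`apoptotic_frac` has no measured value; live-imaging observations show
necrosis-like death as the common rapid outcome with apoptotic fragmentation
in a subset of targets, so the default is 0.3. `bodies_per_cell = 20` keeps
each body at 5% of a cell's calcein on average; with the uniform Dirichlet
split the largest body of a cell is Beta(1, B−1)-distributed, and B = 20
makes the probability that any single body rivals a live cell's intensity
negligible (~10⁻³ per apoptotic death), which is what keeps the intensity
gate clean. Survivors (and all spontaneous-control cells) leak `leak_frac`
(0.15) of their calcein deterministically — the spontaneous release of the
assay, ~15% of maximum, with detergent lysis defining 100%.

Calcein is conserved exactly in every well: supernatant plus particle
content equals the loaded total to float round-off, enforced by computing
the supernatant as the complement.

**Effector cells are not simulated.** They carry no calcein and are
invisible in the fluorescence channel; their only effect is the kill
probability.

## Imaging model

A well's readout sample is the resuspended pellet: `sampled_fraction`
(default 0.4 — 20 μl imaged of the 50 μl resuspension) of the particles are
imaged. Because a declumping-free detector needs dilute fields, the imaged
particles are spread across however many 512×512 frames (2 μm/px) keep each
frame's padded-particle footprint below `max_fill_fraction` (0.24) of the
frame interior — the multi-frame slide scan of a real image cytometer;
counts are pooled over frames. Within a frame, particles are placed
uniformly with pairwise center distance ≥ 1.5 × the mean of the two
diameters and ≥ 24 px from the border. The 1.5 padding keeps the detection
masks of adjacent bright cells from touching (at 1.3 the masks of bright
pairs can bridge, and the resulting merging losses hit dense spontaneous
frames harder than sparse test frames, biasing the count ratio); the border
margin prevents edge-truncated spots from contaminating measured
intensities. In-well particle coordinates are provenance only: physically,
resuspension and slide loading randomize positions.

Each particle renders as an isotropic Gaussian spot with integrated signal
`gain × calcein` counts (gain 200 absorbs exposure time and optics — only
relative intensities matter to gating) and sigma `max(psf_sigma_um,
diameter/4)` (PSF floor 1 μm). The kernel is pixel-integrated (erf) and
window-normalized, so noiseless rendering conserves signal exactly up to
edge truncation. The camera model is the standard Poisson(signal + offset)
shot noise plus Gaussian read noise (offset 100, read SD 3 counts),
quantized and clipped to the bit depth (16). Under these defaults a mean
live cell integrates ~17,000–20,000 counts against a background noise floor
of ~10 counts/pixel; apoptotic bodies integrate ~5% of that. A 2 μm pixel
pitch keeps a 16-μm cell's spot (σ = 2 px) peaked ~12× above the detection
threshold; at 1 μm/px the same cell is so flat that halos corrupt the
background estimate and intensities smear.

## Detection and gating

Background is the sigma-clipped median (3 iterations at 3σ, MAD-scaled);
clipping keeps the estimate independent of how many bright objects the frame
contains, so busy and sparse wells see the same threshold. The default
threshold is background + 5 robust SDs (`k_sigma`); Otsu is available but
unstable when foreground area is tiny. Above-threshold pixels are labeled as
8-connected components; touching cells are not split (no watershed) — the
placement model makes true contacts rare, and this is a stated limitation
for clumpy real samples. Components below `min_diameter_um` (1 μm)
equivalent diameter are discarded: a software floor that removes
sub-resolution specks while deliberately *keeping* apoptotic bodies in the
table, because their exclusion belongs to the intensity gate. Each object's
integrated intensity is the background-subtracted sum over its mask,
clamped at zero.

The live-cell gate formalizes "dimmer than the spontaneous-control target
cells" as the q-th percentile (default q = 5, linear interpolation) of the
pooled spontaneous-control integrated intensities. It is reproducible and
data-driven where the original manual histogram gate was not. Counting is
boundary-inclusive on both intensity and diameter. Because the same ~q% of
live cells falls below the gate in test and spontaneous wells, the excluded
tail cancels from the count ratio.

## Readouts and statistics

* release: `100 × (test − spont) / (max − spont)` on replicate-averaged
  supernatant fluorescence (controls averaged first, per plate-reader
  practice); invariant to any common scaling, so the supernatant sampling
  volume cancels.
* imaging: `100 × (spont count − test count) / spont count`, with the
  spontaneous count averaged over control wells; invariant in expectation to
  the field-sampling fraction.
* Values outside [0, 100] are reported as-is with a QC flag — clamping would
  hide assay failures.
* dynamic range: spontaneous release as % of maximum, and its complement.

In the no-leak, fully apoptotic limit with retention ρ and kill fraction k,
the expected readouts are `100·k·(1−ρ)` (release) and `100·k` (imaging);
the gap `100·k·ρ` is the retention-driven underestimation of the release
assay. The simulator reproduces both to within sampling noise at
n = 10,000 targets/well.

Method comparison uses the Wilcoxon matched-pairs signed-rank test on
(release, imaging) pairs: zero differences dropped (Wilcoxon's convention),
tied absolute differences mid-ranked, the exact null distribution (dynamic
programming over doubled ranks) for n ≤ 25 — paper-scale panels of 15 pairs
fall in the exact regime — and a tie-corrected, continuity-corrected normal
approximation above. The reported W is min(W⁺, W⁻).

## Orchestration and reproducibility

A plate is spontaneous + maximum controls (6 replicates each by default)
plus triplicate test wells per E:T ratio. Per-well seeds derive from
`SeedSequence([master_seed, well_index])`, giving independent yet bitwise-
reproducible wells; seeds are recorded in the results table. The analysis
entry point (`analyze_images`) consumes a plate-map CSV naming per-well TIFF
frames or object tables and is identical to the simulation path from
detection onward; unreadable files are reported per well without aborting
the run. Supernatant fluorescence is supernatant calcein times a constant
(1 AU⁻¹), which cancels in the release formula.

## Problem sizes

Desk-scale defaults are 10,000 targets/well (the wet protocol's 100,000 is a
pipetting quantity, not an imaging requirement) and 512² px frames. The
repeated Monte-Carlo studies in the test suite run at reduced scale chosen
as the smallest sizes whose sampling noise is far below the effects under
test: 1,500 targets/well for the 100-run retention-monotonicity study
(gap increments of ~15 points vs ~2-point noise) and 500 targets/well for
the 100-run donor-panel study (a ~30-point method gap vs ~4-point pair
noise).

## What the synthetic data does not capture

* Kinetics: no time course, serial killing, or conjugation dynamics.
* Geometry: dispersed, non-overlapping particles; real apoptotic bodies
  cluster near their parent cell and real samples clump (no watershed is
  provided, so clumped real images would undercount).
* Optics: single channel, Gaussian spots, no photobleaching, flat field,
  no focus drift.
* Biology: no density-dependent killing effect — halving target density
  leaves expected lysis unchanged by construction, unlike real assays where
  density changes NK efficiency; donor variability is a single potency
  scalar on kill fractions.

Passing tests therefore demonstrate internal consistency of the pipeline
and formulas under the stated forward model, not instrument-level accuracy
on real images.
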