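# Methods

## Problem and approach

Krill fishing vessels run downward-looking echosounders continuously while
searching for and catching Antarctic krill. Air-breathing krill predators
that dive beneath a vessel leave characteristic signatures in the recorded
volume backscatter (Sv, dB re 1 m⁻¹): penguins and Antarctic fur seals
release air during ascent, producing thin comet-like **bubble trails**
(local vertical extent ≲ 2 m), while the bodies and lung air of baleen
whales produce intense compact blobs **3–20+ m** tall. Detecting these
signatures and normalizing them by observation effort yields a
**predator–vessel encounter rate** — minutes of predator presence beneath
the vessel per hour of analyzed echogram — that can be aggregated in time,
over lon/lat grids, and around predator colonies.

divetrace implements that chain as five composable stages plus a synthetic
scene generator that provides pixel-accurate ground truth, so the entire
pipeline is testable without any acoustic archive.

## Standardization

Raw records are irregular in ping time. They are regridded to **1 s ×
0.5 m** (linear interpolation of Sv *in dB* along time where the ping
interval exceeds 1 s; nearest-bin-center assignment in depth), split into
consecutive non-overlapping **10-min × 500-m** windows anchored at the
record start (shortfalls padded with NaN, never zero — padding must not
masquerade as quiet water), and mapped to grayscale by the fixed affine
window **−90 dB → 0.0, −20 dB → 1.0** with clipping. The result is a
600 × 1000 echogram per window; pixel (c, r) covers the half-open cell
[c, c+1) s × [0.5r, 0.5(r+1)) m.

Interpolating in dB rather than linear backscatter is the simpler reading
of "linear interpolation of volume backscatter" for display-oriented
processing and keeps the grayscale map exactly affine; gaps longer than a
configurable threshold (default 10 s) are still interpolated but flagged.

## Segmentation

Pixels are classified into five classes: background, seafloor, krill
swarm, whale, bubble trail.

**U-Net.** A configurable encoder–decoder network (per level two 3×3
convolutions + ReLU, 2×2 max-pooling, nearest-neighbour upsampling,
channel-concatenated skips, 1×1 output convolution, softmax), implemented
directly on NumPy with explicit backpropagation and Adam. We chose a plain
U-Net over a multi-resolution variant: at the scales this package trains
at, block topology is not the binding constraint, and the plain form keeps
the hand-written gradients auditable. The loss is pixel-wise categorical
cross-entropy with per-class weights, default **(1, 1, 1, 10, 1)** — the
whale class is up-weighted 10:1 because whales are by far the rarest class
in annotated echograms (~0.002 % of pixels). The output-layer bias is
initialized at the log class priors of the training masks, so the network
starts from the marginal label distribution instead of spending its first
epochs learning it — with short training budgets this removes most of the
run-to-run variance between weight initializations. Training keeps the
epoch checkpoint with the best validation loss.

The full-scale configuration (4 levels, 256-px tiles, 100 epochs, batch
20) exists as the default `UNetConfig` but is not exercised by the test
suite; the package's **reduced configuration** — 2 levels, 8 base filters,
64-px tiles, 15 epochs, batch 20, Adam at 2·10⁻³ — trains on one CPU in
about two minutes on 200 synthetic tiles. At inference, echograms larger
than the tile are covered by overlapping tiles and overlapping
probabilities are averaged (the least surprising blend).

**Decision rule.** A pixel receives the highest-probability class among
the classes whose probability meets their per-class threshold; if none
does, background. With all thresholds 0 this degenerates to argmax. Exact
ties resolve to the rarest class (whale > bubble trail > krill swarm >
seafloor > background), protecting the classes the loss deliberately
up-weights. Optimal thresholds are the F1-maximizers of per-class
one-vs-rest precision–recall sweeps on validation data.

**Reference segmenter.** A deterministic rule-based segmenter (Sv
threshold → 8-connected components → classification by shape and
intensity: near-full-width deep band → seafloor; per-column extent ≤ 4 px
with net ascent → bubble trail; ≥ 3 m tall and intense → whale; else
krill) serves as an independent oracle: on noise-free synthetic scenes it
recovers planted objects essentially perfectly, which lets every
downstream stage be tested against ground truth without training a network
first.

**Augmentation.** Random crops (scale 0.6–1.0), horizontal/vertical flips,
rotations (±15°) and elastic deformations, with every geometric transform
applied identically to image and mask (nearest-neighbour for masks so
labels stay categorical). The transform families are standard; the
parameter ranges are this package's own defaults.

## Dive events

Connected components (8-connectivity — bubble trails are thin diagonals
that 4-connectivity would shatter) of the two predator classes become
polygons; components smaller than `min_pixels` (default 6) are dropped as
speckle. Measurements use inclusive pixel spans, so a single pixel is a
1-s, 0.5-m detection:

* duration = (col_max − col_min + 1) × 1 s,
* acoustic height = (row_max − row_min + 1) × 0.5 m,
* timestamp = window start + col_min; position interpolated from the
  vessel track at that timestamp.

Acoustic height assigns whale-class detections to taxon groups: < 2 m
seal-like (fur seals are ~2 m long, usually tilted relative to the beam),
2–3 m ambiguous, ≥ 3 m whale-like (baleen whale body diameter 3–6 m).
Bubble trails are left taxonomically unsplit — penguins vs fur seals is a
question of regional context, not acoustics. Events spanning adjacent
10-min windows are not merged (windows are processed independently); a
window-boundary flag lets users post-merge.

QC flags (a CSV of event-id/decision pairs, mirroring a manual review of
per-detection control plots) mark events as removed without deleting them;
removed events are excluded from every downstream rate.

## Encounter rates

The observation ledger holds, per echogram window, the analyzed hours
(non-padded columns only) and the vessel position. Rates divide predator
minutes by observation hours per time bin (default 7 days, configurable —
a reporting choice, not a scientific constant) or per half-open lon/lat
grid cell anchored at integer multiples of the cell size (regional
defaults 0.04°, 0.03°, 0.075°). Bins with zero observation hours report a
*missing* rate, never zero. For display, log₁₀(rate + 1) keeps zero rates
finite.

Vessel activity is classified from track speed: **fishing between 0.3 and
5 kn inclusive** (bounds inclusive by our choice; the window itself
excludes stationary/offloading below and steaming above), with externally
supplied activity labels taking precedence where available. Excluding a
period removes it from numerator *and* denominator; events at a status
transition follow their start timestamp.

Colony exposure uses great-circle distances (haversine, R = 6371 km,
cross-checked against a spherical-law-of-cosines oracle to < 1 m) to the
nearest colony; events and hours are stratified inside/outside a radial
30-km buffer (the approximate maximum foraging range of breeding
penguins; true coastline buffering is out of scope but pluggable) and
before/after a management cutoff date (default 2018-07-01). The
within-15-km share of bubble-trail minutes is reported alongside. Krill
consumption equivalents use 100 kg per penguin per summer. Fleet
diagnostics cover the median inter-vessel distance at matched timestamps
and observation hours by local hour-of-day.

## Synthetic scenes

The generator paints objects onto the standard grid and samples records
from that canvas, so planted geometry is exact by construction:

* background: Gaussian noise in dB, N(−85, 3) by default — plausible for
  quiet 120/200 kHz open water; combined with signal by elementwise max so
  planted intensities are preserved exactly;
* krill swarms: diffuse ellipses, −68 dB;
* bubble trails: ascending streaks of per-column width 1–4 px, −52 dB at
  the head fading 10 dB toward the tail; the ascent rate is capped below
  the trail width per column (physically, bubble rise speed ≲ 1.5 m/s),
  which also keeps the rendered streak 8-connected;
* whale dives: compact ellipses ≥ 3 m tall, −42 dB;
* seafloor: a strong (−38 dB) band, optionally sinusoidal.

No dB value for any class is an empirical constant — the source data
give none — so intensities are calibration knobs fixed once at plausible
relative prominences. Overlapping plants resolve by scatterer strength
(whale > bubble trail > krill > seafloor), logged. Irregular pings,
jitter, and random sample dropout (NaN) exercise the regridding path. All
randomness flows from one seed per scene; identical configs give
bit-identical records, masks and event tables.

Three ready-made configurations:

* **corpus-like** (600 × 1000): area-targeted placement until the planted
  pixel budget per class is met, reproducing the annotated-corpus shares
  of ~87 % background / ~10 % krill / ~1 % bubble trails (trails must be
  dense and may overlap; thin streaks cannot reach 1 % otherwise);
* **oracle** (noise-free): well-separated objects of every class for
  exact-recovery tests;
* **training tiles** (64 × 64): class-balanced small scenes for the
  reduced network.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: sonar-equation physics (beam pattern,
TVG, absorption, the ES60 triangle-wave error), multi-frequency dB
differencing, realistic seafloor texture and noise spikes, surface bubble
sweep-down layers, and the visual ambiguity between faint predator
signals and krill edges that drives manual QC on real echograms.
Performance numbers on synthetic scenes are upper bounds.

## Numerical choices and problem sizes

* Missing marker is NaN end to end; padding is forced to background in
  every mask product.
* Evaluation per class is one-vs-rest pixel precision/recall/F1 with
  0/0 → 0; threshold sweeps use a 0.05 grid.
* Test and acceptance runs use the reduced scales chosen for this
  package: 50 noise-free 300 s × 120 m oracle scenes, a 250-tile
  (200 train / 50 held-out) 64-px training corpus, and a 10-scene
  end-to-end demonstration; these sizes make the whole suite reproducible
  on a single CPU.
* The spec of the corpus split (floor of fraction × n) reproduces
  821/353 from 1,174 at 0.7.

## Known limitations

* The NumPy U-Net is adequate for the reduced scales but not for
  archive-scale (200,000-window) inference; swapping in a GPU framework
  behind `UNetSegmenter` would not change any interface.
* Bubble trails are not split penguin vs fur seal; regional metadata is
  carried but no taxon is assigned.
* VRZ geometry is radial around colony points, not buffered coastline.
* No hypothesis tests are attached to before/after comparisons; the
  package reports stratified rates descriptively and leaves inference to
  the user.
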