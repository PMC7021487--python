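# Methods

This note documents the models behind `mtquant`'s three measurement
pipelines and its synthetic-data generators: what is simulated, what is
assumed, which parameters matter, and where the numerically delicate
choices lie.

## The sliding assay and its model

The experiment this package quantifies photoconverts tubulin within a
diaphragm-confined region of a cell expressing photoconvertible
α-tubulin, then collects one frame per minute for about ten minutes.
Kinesin-driven microtubule–microtubule sliding carries converted
microtubules out of the zone; the per-frame motile fraction
f(t) = (converted pixels outside the initial zone)/(all converted pixels)
rises, and the slope of its linear portion is the sliding rate.

### Simulator (`mtquant.synthetic.simulate_sliding_movie`)

Microtubules are **rigid line segments**; no bending, polymerization or
treadmilling is modelled, because the statistic measures translocation
only. Conversion clips each filament to its geometric intersection with a
disc-shaped zone at t = 0; a fraction `motile_fraction_true` of filaments
then translocates rigidly along its own axis at constant `velocity`
(direction sign random). Ground truth is computed from the unrendered
geometry as exact segment–disc chord lengths, so every rendered movie
carries an analytic motile-fraction curve.

Rendering follows a standard camera model: sub-pixel line splatting
(energy-conserving bilinear deposition at 0.2 px steps), Gaussian PSF blur
(σ = 1 px), per-frame multiplication by (1−bleach_rate)^t, then noise.
The default noise is **Poisson shot noise** at ~100 expected photons per
filament-pixel, the dominant noise source of photon-limited EMCCD
imaging; zero-mean Gaussian read noise is available but note that
clipping it at zero (intensities are non-negative) adds a small constant
to frame sums and therefore perturbs ratio bleach correction.

Default geometry (192×192 px at 0.1 µm/px, zone radius 4 µm, 20
filaments of 8–12 µm, 11 frames at 1/min) was chosen so that the assay
operates in the regime the measurement assumes:

* **Filaments span the zone.** Each filament is placed along its sampled
  line so the converted segment is a full chord with both ends on the
  zone boundary. Chords then begin leaving the zone immediately and the
  outside length grows exactly linearly at the translocation velocity —
  no lag phase from filament ends buried inside the zone. (With free
  placement, buried ends produce a lag that contributes nothing at
  velocity v but substantially at 2v, making the ground-truth fold change
  superlinear in velocity; long microtubules relative to a small
  conversion spot are also the physically typical situation.)
* **Filaments are individually resolvable.** At high filament density the
  frame-0 Otsu threshold falls between single-filament and
  overlapping-filament intensity rather than between background and
  signal, and translocated single chords become invisible. The default
  density keeps total chord coverage well below the zone area.

With these conditions the ground-truth fold change between velocity v and
2v groups is 2.00 and the per-movie slope coefficient of variation is
≈ 0.1.

### Measurement chain (`mtquant.sliding.analyze_movie`)

1. **Bleach correction** — simple ratio: frame t is scaled by S₀/Sₜ where
   Sₜ is the frame's summed intensity within the cell mask (whole frame if
   none). Exactly removes any global multiplicative decay, is idempotent,
   and parameter-free.
2. **Denoising** — optional 3×3 median despeckle plus a Gaussian smooth
   (σ = 1 px, default on). The smooth is not cosmetic: bleach correction
   amplifies late-frame noise by 1/(1−b)^t, and with a threshold fixed
   from frame 0 the flicker of dim sub-threshold pixels is asymmetric
   (noise can only push them above the line), which otherwise drifts the
   null motile fraction upward by ~1–2% of a typical control slope per
   movie. Pixel-averaging removes the effect; it is the deterministic
   analogue of segmenting smoothed probability maps rather than raw
   pixels.
3. **Segmentation** — Otsu threshold computed on frame 0 and **held fixed**
   for all frames. Per-frame thresholds would couple the criterion to
   signal dilution as converted tubulin spreads, biasing the motile
   fraction; the global-stack, fixed-value and smoothed-probability-map
   variants are provided as alternatives.
4. **Initial zone** — either the closed and hole-filled frame-0 mask
   (morphological closing radius 2 px) or a user disc matching the
   diaphragm ROI. Analyses of simulated data use the disc, which is the
   zone the ground truth is defined against.
5. **Series and fit** — frames whose mask is empty are dropped (never
   interpolated; fabricating counts would bias the slope). The "linear
   portion" is chosen objectively: among contiguous windows starting at
   t = 0 with at least 5 points, the longest with R² ≥ 0.9, else the
   best-R² window; OLS slope in fraction/min. A constant series is
   reported as slope 0 with R² = 1 by convention and flagged degenerate.
6. **Normalization** — slope / mean(control slopes of the same batch), so
   control normalized rates average exactly 1 per batch, matching how
   sliding assays are conventionally reported (fold of control).

## Colocalization

The readout is area overlap on binary masks, not intensity correlation,
because the target quantity is "% of microtubule area decorated":
percent = 100·|MT ∧ Pav|/|MT| with per-channel Otsu thresholds (fixed
values configurable). Restricting both numerator and denominator to the
microtubule mask excludes nuclear or cytoplasmic pools of the second
channel by construction.

An **empty-channel guard** protects the second channel: Otsu always splits
a histogram, even of pure noise, so the guard asks whether the channel
carries spatially structured signal at all — the fraction of image
variance surviving a 1 px Gaussian smooth is ≈ 1/(4π) ≈ 0.08 for
pixel-independent noise and ≥ 0.5 for any PSF-blurred structure; below
0.25 the channel is declared empty (0% with a warning). After the guard
(which must see the raw image — smoothing would make noise itself look
structured), each Otsu-thresholded channel is Gaussian-denoised (σ = 1 px)
before thresholding: with raw pixels, independent noise makes the two
channels' masks disagree on ribbon edges even where the underlying signal
is identical, deflating a fully decorated image to ~97% instead of
~98.5%.

The simulator places channel-2 signal on an exact share of channel-1
filament pixels, in contiguous runs of 5 µm (decoration occurs in
stretches, and run granularity sets the quantization of the achievable
fraction); both channels are then blurred and noised identically. Blur
lengthens decorated runs by roughly one PSF width at each end after
thresholding, which bounds the expected recovery bias at ≈ +1 point for
fractions near 25–50% with the default run length; at fraction 1.0
residual mask-edge disagreement between the channels keeps recovery near
98–99%, not 100%.

## Arbor morphometry

Arbors are grown as random planar trees by recursive tip branching: each
branch event splits one tip into two daughters (fork half-angles 14–52°),
so internal nodes of degree ≥ 3 equal the number of branch events.
Daughter segments must stay in frame, keep ≥ 6 px from all existing
structure (dendritic-arborization dendrites self-avoid, and separations
below the PSF-plus-morphology scale would not be resolvable as distinct
branches), and keep branch points ≥ `min_branch_separation` apart;
failures shrink the proposed segments and retry, erroring after 100
attempts. Ground-truth length is the exact sum of segment lengths; the
rendering is the 1 px rasterization, dilated (radius 1) and blurred
(σ = 1 px).

The measurement chain is ridge enhancement → Otsu → closing(1) →
small-component pruning (< 5 px) → skeletonization → graph measurement.
The tubeness filter is the Hessian ridge measure max(0, −λ₂) of the
Gaussian-smoothed image, computed with scipy Gaussian-derivative kernels
and the closed-form 2×2 eigenvalue (inputs are mean-centred first so the
truncated kernels map constant images to exactly zero). The enhancement
scale (σ = 1.5 px) and closing radius (1 px) are matched to the ~3 px
tube width: oversized scales fatten the ribbons until nearby branches
fuse, which creates skeleton loops and spurious junctions.

**Length** is measured per skeleton branch by resampling the pixel chain
at 5 px chords and summing Euclidean chord lengths. The classical
1/√2-weighted step sum is kept as an option but systematically
overestimates oblique paths (up to ~8% at 22.5°, ~5.5% averaged over
angles), which would exceed the package's 5% accuracy budget; chord
resampling is exact for digital straight lines at 0° and 45° and within
~1–2% at intermediate angles. **Branch points** are skeleton pixels with
≥ 3 8-neighbors, merged within a 2 px cluster radius because thinning
produces 2–3 adjacent high-degree pixels at one anatomical junction.

## Statistics

Summaries are mean ± SEM (sample SD, n−1) with t-distribution 95% CIs.
Pairwise tests default to the classic pooled-variance Student's t (Welch
optional). The one-way ANOVA post-hoc uses, for Sidak, raw p-values from
pairwise t statistics with the pooled within-group mean square on N−k
degrees of freedom, adjusted as 1−(1−p)^m where m is the number of
*requested* pairs (experiments typically compare selected pairs against
control, and m belongs to the design, not the data); Tukey uses the
studentized-range distribution over all groups. Because the pairwise
comparisons share data, Sidak is slightly conservative: the simulated
3-group null familywise error sits near 4.5% at nominal 5%. Blot
quantification is (phospho/total)/(control phospho/control total), which
cancels loading and IP-efficiency differences by construction.

## What the synthetic data does and does not establish

The generators emulate PSF blur, shot noise, photobleaching, contiguous
decoration and self-avoiding arbor growth, with exact ground truth. They
do **not** model filament curvature or dynamics, cytoplasmic
autofluorescence background, stage drift, spectral bleed-through, 3D
structure, or densely bundled microtubule networks in which single
filaments are unresolvable. Passing recovery tests therefore shows the
measurement chain is unbiased and correctly calibrated in the resolvable,
drift-free regime; it does not certify performance on crowded or drifting
real recordings, where registration and trained segmentation (which the
deterministic smoothed-threshold stand-in replaces) carry real weight.

## Problem sizes

The test suite and the reproduction script run on one CPU in a few
minutes total: sliding groups of 15 + 15 + 20 movies (192² px, 11
frames), 8 images per decorated fraction, 20 arbors (512² px), and 3000
ANOVA null simulations — sizes at which every recovery statistic above
has comfortable Monte-Carlo margin against its tolerance.
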