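# Methods

## Problem and model

A gas bubble carried through an ultrasound imaging plane appears, for a few
frames, as a bright compact blob in the 2-D image. Because flow velocity is
unknown, no attempt is made to reconstruct the bubble's path: each bubble is
summarised by the sequence of its per-frame cross-sections ("slices") and
reduced to a single point in (x, y, t) with an estimated radius. The sphere
model ties the per-frame geometry together through the chord law: a sphere
of radius R crossed by the plane at axial distance d shows a circular
section of radius r(d) = sqrt(R² − d²), so the largest observed slice radius
estimates the sphere radius and (4/3)πR³ its volume. Using the largest
chord rather than the mean avoids needing the (unknown) crossing speed.

Coordinates: image origin top-left, x = column (lateral), y = row (axial,
away from the transducer), 0-based; physical positions in mm via the
per-axis calibration, time = frame_index / frame_rate in seconds.

## Detection

Candidates are 8-connected components of {ROI pixels ≥ threshold}
(8-connectivity because anti-aliased blob edges fragment under
4-connectivity). A candidate survives screening iff

* area ∈ [`area_min_px`, `area_max_px`] (default 2–2000 px²),
* minor/major axis of its second-moment ellipse ∈
  [`aspect_ratio_min`, `aspect_ratio_max`] (default 0.33–1.0) — a bounded,
  orientation-free aspect definition,
* circularity 4πA/P² ≥ `circularity_min` (default 0.5), with the perimeter
  P measured by boundary-chain counting (Moore trace of the outer contour,
  axial steps 1, diagonal steps √2; this makes a rasterized disc score ≈ 1),
* its boundary is a single closed contour (no interior holes).

The last two rules operationalise the requirement of a continuous, smooth
boundary; none of the numeric defaults is a claim about any particular
machine — all are configuration.

**Automatic threshold.** Otsu's criterion on ROI pixels pooled over the
first min(30, n) frames, refined to the intermeans (Ridler–Calvard) fixed
point: with very few bright pixels the raw Otsu split can settle at the edge
of the background tail, while the intermeans threshold sits midway between
the class means, inside the empty intensity gap. Emboli are sparse, so if
the split would label more than 25% of ROI pixels as foreground the scene is
treated as background-only and the threshold is placed above the brightest
pooled pixel with a 3-standard-deviation margin (later frames sample deeper
into the speckle tail than the estimation window did). Both paths shift
with a uniform intensity offset, which is what makes detection counts
invariant under gain changes.

**ROI update (wall-gradient method).** Every `roi_update_period` frames
(default 25), 72 radial rays from the ROI centroid search ±20% of the
previous boundary radius for the strongest *positive* outward intensity
gradient — the dark-lumen to bright-wall edge; using the gradient magnitude
instead would lock onto the far side of the wall. The peak is refined by
parabolic interpolation, stepped 1 px inward (the peak of a blurred step
sits mid-edge, and the ROI must exclude the wall pixels themselves),
smoothed by a circular 5-point vertex moving average whose radial shrinkage
is compensated analytically, and accepted only if the polygon stays simple.
If fewer than half the rays find a peak above the noise floor
(max(2, 3·median |gradient|) grey-levels/px), the previous ROI is kept —
this makes the update a no-op on featureless frames.

## Reconstruction

**Linking.** Frames are processed in order; the slices of each frame are
assigned to open tracks by the Hungarian algorithm with cost = squared
centroid distance, gated at `max_link_distance` (default 3 mm — generous
relative to the ~0.25 mm/frame lateral wobble motion); unmatched slices
open tracks, and a track closes after `max_frame_gap` (default 1) missed
frames. A chain whose slice-radius profile pinches below 0.4× the maxima on
both sides (with ≥ 2 slices per side) is split there: a single bubble's
chord profile rises and falls once, so a deep interior minimum means two
successive crossings at the same spot were chained.

**Phantom-echo merging.** In a low-impedance water path each bubble can
produce reverberation copies displaced away from the transducer. An echo is
an axially displaced, attenuated *copy*, and the merge test checks exactly
that, pairwise over the frames two tracks share: ≥ 50% frame overlap
(of the shorter track), mean per-frame lateral separation ≤ 1 mm, mean
axial separation ≤ 4 mm, mean intensity ratio ≤ 0.9 (decay ~0.7 per copy),
similar radius profiles (mean per-frame difference ≤ 50% of scale), and a
near-constant separation vector (std ≤ 0.3 mm per axis — the echo rides its
bubble's wobble, independent bubbles drift apart). Merging is transitive;
within each merged group the brightest member survives, and a member is
absorbed as its echo only if it is both attenuated and axially below the
survivor — otherwise it was bridged in (e.g. a real bubble crossing near a
neighbour's echo) and is restored as an independent track. Absorbed slices
move to the surviving track's `echo_slices`: nothing is deleted, but echoes
do not contribute to the position/radius estimate. The merge stage can be
switched off (`merge_phantoms_enabled`), since the artifact is specific to
low-impedance media.

**Estimation.** position = arithmetic mean of slice centroids (x, y);
time = mean slice time; radius = largest slice radius with a fused-slice
guard — in a track of ≥ 4 slices whose top radius exceeds 1.4× the
runner-up, the runner-up is used, because near the diameter the chord
profile is flat and a 40% jump means the brightest slice merged with a
neighbouring object.

## Reporting

total count = number of tracks; count rate = tracks whose mean time falls in
the trailing `report_window` (default 10 s) divided by the window;
cumulative air volume = Σ (4/3)πr³. The per-frame air fraction (Σ slice
areas / ROI area, both mm²) is a 2-D proxy for the volume percentage of the
lumen — a single plane carries no per-frame 3-D volume, so both quantities
are emitted and the proxy is labelled as such. The radius histogram uses
0.1 mm bins over 0–2 mm, covering the simulated 0.1–1.5 mm population;
radii outside the edges are clipped into the end bins so counts always sum
to the track count.

## Dual-stream validation

Two track streams are matched one-to-one by minimising
Σ [w_pos‖Δposition‖² + w_time Δt² + w_radius Δr²] over matchings of maximal
allowed size, where a pair is allowed only if its cost ≤ `gate_cost`.
Defaults normalise each term by a typical spread — w_pos = 1/(1.4 mm)²,
w_time = 1/(0.4 s)², w_radius = 1/(0.2 mm)² — making the three terms
commensurate, with gate 9 ≈ a 3σ joint residual. The matching is solved
exactly (Hungarian with a dominating sentinel on forbidden pairs), so it
equals exhaustive enumeration on small instances. Reported statistics:
Pearson r of matched radii; sample SDs (ddof = 1) of the planar Euclidean
position difference and of the signed time and radius differences.

## Synthetic rig

The simulator emulates a rise-chamber validation experiment at appearance
level (it exercises the image-analysis chain, not wave physics):

* **Population**: `n_bubbles` radii i.i.d. uniform on 0.1–1.5 mm (the
  generated range; the true rig distribution is unpublished, so
  distribution-sensitive statistics are bounds, not point values), crossing
  times uniform over the run, lateral positions uniform in a disc of 0.7×
  the lumen radius.
* **Kinematics**: constant rise speed (default 5 mm/s) through the plane,
  so a bubble is visible for 2R/v seconds with chord-law slice radii;
  sinusoidal lateral wobble, default amplitude 1 mm per axis with random
  phase and 1 s period.
* **Appearance**: a bubble highlight is a disc of size-independent peak
  intensity (default 220) with a 1 px anti-aliased edge — bubbles are
  strong scatterers, weak in extent rather than amplitude, and the sharp
  edge keeps the thresholded extent equal to the chord radius for any
  threshold between background and peak. The background is multiplicative
  speckle (exponential, mean `speckle_scale`, default 30) low-pass filtered
  by the PSF (σ 0.15 mm), plus a bright wall ring just outside the lumen;
  a uniform gain offset is added and the result clipped to 8 bits.
* **Phantom echoes**: with probability `phantom_prob`, copies at +3 and
  +6 mm axially with peak decaying by 0.7 per copy.
* **Optical truth**: synthesised directly from the ground truth (position
  at crossing time on the wobbled trajectory), with optional small Gaussian
  jitter; at zero jitter it is exact. The real optical camera ran at a
  much higher frame rate than the ultrasound stream, which is why truth is
  generated in continuous time rather than rendered.
* **Determinism**: every random draw derives from `seed` (per-frame
  child generators), so runs are reproducible regardless of how frames are
  consumed.

Problem sizes: the full validation regime uses 1030 bubbles over 400 s at
25 Hz (10 000 frames of 256×256 px at 0.1 mm/px, ≈ 0.8 bubbles concurrently
in view); parameter-recovery checks use 200 temporally disjoint bubbles
(spacing 1.8 s, rise 2 mm/s so even 0.1 mm bubbles subtend ≥ ~1 px in some
frame) on 128×128 frames. The rise speed is chosen for sampling adequacy
at 25 Hz, not as a hydrodynamic claim.

What the simulator does **not** model: acoustic wave propagation, intensity
dependence on insonation frequency/power or bubble interactions,
out-of-plane wobble, non-spherical deformation, and blood as the medium.
Passing tests therefore demonstrate the correctness of the image-analysis
logic under controlled appearance-level conditions, not clinical
performance.

## Numerical choices and degenerate inputs

* Linking/matching ties are broken by the assignment solver's deterministic
  order (effectively lowest id); all costs are continuous so ties have
  measure zero in the simulated regimes.
* A single-pixel region has an undefined second-moment ellipse; its aspect
  is defined as 1 and its circularity as ∞ (the area rule, not the shape
  rules, governs point-like regions).
* A fully saturated ROI raises a degenerate-input error; a uniform ROI
  yields a threshold just above the constant, hence zero candidates.
* Residual statistics require ≥ 2 matched pairs, Pearson r non-zero
  variance; both raise a dedicated error otherwise.
* px→mm→px round trips are exact to < 1e-9 mm; report JSON round-trips to
  1e-9.

## Known limitations

* Radius accuracy degrades below ~2 px chord radius; at 0.1 mm/px this
  means bubbles under ~0.2 mm are found but coarsely sized, and sub-pixel
  chords near the visibility edge can be missed entirely.
* Two bubbles overlapping in the image fuse into one component; the
  fused-slice radius guard and pinch splitting mitigate but cannot resolve
  genuine occlusion.
* The phantom copy test can in principle absorb a real bubble that is
  dimmer, axially below, and trajectory-locked to another — geometrically
  indistinguishable from an echo in a single plane.
* The wall-gradient update assumes a star-shaped lumen around the ROI
  centroid and a wall brighter than the lumen.
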