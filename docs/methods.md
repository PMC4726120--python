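# Methods

This note records the models, algorithms and numerical choices behind
the package, in enough detail to reproduce or modify them.

## Striation geometry

The laser pattern is a set of `lines_per_field` equally spaced
horizontal lines across the field, so the nominal gauge (distance
between stripe centers) is `D_nominal = image_rows / lines_per_field`
pixels. A stripe band is modelled as exactly `width_px` consecutive
pixels, anchored so the band around a center *c* covers columns
`c − (w−1)//2 … c + w//2`; the stripe width is an acquisition constant
set by the hardware and is never fitted. Stripe centers are taken at
every integer multiple of the gauge whose band intersects the nucleus
bounding box, which makes the objective exactly periodic in the offset
*P*; *P* is therefore reported canonically in `[0, D)`, and offset
comparisons should use circular distance mod *D*.

## Segmentation

Live-cell reporter nuclei span an easily 10-fold range of baseline
intensity, which defeats any single global threshold. The cascade
sweeps intensity thresholds geometrically (factor
`threshold_decay_factor`, default 0.9) from the intensity at
`threshold_start_quantile` (0.995) down to the intensity at
`threshold_floor_quantile` (0.5). At each level, 4-connected
components that pass the gates — area in `[min_area_px, max_area_px]`,
solidity ≥ `min_solidity` (0.90), optionally not touching the border —
are accepted, hole-filled and their pixels frozen out of lower levels,
so each nucleus is captured at the highest threshold at which it is a
complete, compact object. Defaults (`min_area_px = 500`,
`max_area_px = 15000`) suit a 40× objective; the synthetic-scene tests
pass gates sized for their smaller nuclei.

Acceptance at "the first level where the gates pass" systematically
under-segments dim nuclei (the component crosses `min_area_px` before
reaching its full extent). A refinement pass therefore re-thresholds
each accepted nucleus at its own local level — the midpoint between the
nucleus's median intensity and the local background median, computed in
a dilated bounding box with other nuclei excluded — and keeps the
refined component if it still passes the gates. This is what "local
thresholds" means here: one threshold per nucleus, chosen from its own
surroundings.

Fixed-sample (immunofluorescence) mode applies the identical cascade to
a Hoechst DNA-counterstain channel and measures MS on the signal
channel with those masks; tracking is disabled.

## Tracking

Striped nuclei can fall to background between stripes, so whole-frame
re-thresholding loses them. Each nucleus is instead re-found inside
its previous bounding box dilated by `search_radius_px` (default 25).
A full threshold sweep of that neighbourhood (floor lowered to the 0.3
local quantile, no freezing) yields candidate components, gated on
solidity and on area between 0.3× and 3× the previous mask's area;
candidates are ranked by area consistency (|log area ratio|), then
centroid distance, and must lie within the search radius.

The accepted candidate *positions* the nucleus; the mask itself is the
frame-0 mask translated rigidly to the candidate centroid, with the
integer shift refined over a ±2 px window by maximising total intensity
inside the placed mask. The reason the mask is a rigid template rather
than the thresholded candidate: a threshold-drawn mask follows the
intensity pattern and preferentially omits dim inter-stripe pixels,
which biases MS upward by as much as +0.2 at strong striation. The
template keeps region membership intensity-independent; slow shape
change is absorbed downstream by the per-frame stripe refit. The cost
is that genuine shape change is not reflected in the mask — a known
limitation for long acquisitions of highly motile or dividing cells.

When no candidate qualifies, the previous mask is carried forward
rigidly for up to `max_carry` (2) frames, after which the track is
lost; lost tracks are never resurrected. Conflicts are resolved
nearer-centroid-first (ties to the lower nucleus id), and no pixel is
claimed by two tracks in one frame.

## Orientation and stripe fitting

The rotation angle comes from the Radon transform of the nucleus
sub-image on a 1° grid over [0°, 180°), after three preparations: the
in-mask mean is subtracted (the nucleus outline otherwise dominates the
sinogram and the ellipse long axis wins over faint stripes), the
magnitude of the residual is taken (bright recruitment stripes and dark
bleached stripes both become positive ridges), and a σ = 1 px Gaussian
smoothing is applied (raw argmax is biased off axis-aligned angles by
interpolation spikes of up to 3°). The angle of the global sinogram
maximum wins, ties toward the smallest angle; a numerically flat
residual (homogeneous nucleus) returns angle 0 directly, which is
harmless because MS is rotation-independent for homogeneous nuclei.
Rotations by multiples of 90° use exact array transposition; other
angles use bilinear interpolation for intensities and nearest-neighbour
for the mask.

`F(D, P)` is the ratio of mean stripe-band intensity to whole-nucleus
mean intensity: 1 for a homogeneous nucleus, maximal when the bands sit
on the stripes. The fit exhaustively evaluates all integer gauges in
`[0.5, 1.5] × D_nominal` and offsets within `±D_nominal/2` of an anchor
column — the column of maximal per-column intensity sum for
recruitment, or of minimal per-column mean for bleaching, where the
argmin of F is taken instead so the fit locks onto the dark bands.
Candidates whose bands cover less than 0.4 × (width/D) of the mask area
are excluded: a band grazing a few boundary pixels can take an extreme
mean and hijack the search. Ties break toward the smallest D, then the
smallest P, so the fit is deterministic.

Because the grid search selects the extremum, measuring MS on the same
pixels would inherit the selection noise (an upward bias of order +0.1
at SNR 10). The search therefore runs on a copy of the rotated image
smoothed along the stripe axis (σ = 2 px; columns keep their
stripe/non-stripe identity, so the clean-data optimum is unchanged)
while MS is always measured on raw intensities.

## MS and curve parameters

`MS = (J_meas − J_expt)/J_expt` with
`J_expt = SID(mask) · area(stripe region)/area(mask)`. MS is exactly
invariant under positive intensity rescaling, bounded below by −1, and
zero for a homogeneous nucleus; an all-zero nucleus has no defined MS
and yields a flagged record, as do frames where the fit fails. Flagged
records are excluded from curves and statistics, never imputed.

DDR curves: Amp = max MS (earliest time wins ties → Tpeak), Relax = OLS
slope over strictly *t* > Tpeak; when the maximum falls on the last
observed time point the curve is marked un-peaked and the slope window
falls back to *t* > 30 min. Relax30 always uses *t* > 30 min (strict;
configurable). FRAP curves: Amp = min MS; Tpeak is not reported (the
minimum is reached immediately after bleaching); Relax30 and Relax are
the slopes over the inclusive windows [1, 30] and [1, 60] min. Windows
with fewer than two points give NaN slopes with an explicit point
count. Median curves take the per-timepoint median over unflagged
values (midpoint convention for even counts) with *n* reported per
timepoint.

## Statistics

Group differences per parameter use the Kruskal–Wallis rank test
(mid-rank tie correction, χ² approximation with k−1 df; a label-
permutation p-value is available for very small samples). α = 0.05
throughout, no multiple-testing correction across the four parameters —
the false-positive guard is replicate concordance: with two biological
replicates an effect is reported only if both are independently
significant in the same direction. Direction is the sign of (treated
median − mock median), coded up/down/ns. `min_cells` defaults to 100
per group, matching the scale the assay is designed for; pass a smaller
value for exploratory data. The fully tied degenerate case returns
H = 0, p = 1.

## Synthetic scenes

The generator renders what the analysis assumes and nothing more:
flat-top elliptical nuclei (axes 9–14 px, aspect ≤ 1.4, random
orientation) on a uniform background of 10, baselines log-uniform over
a 10× range (50–500), horizontal stripes fixed in field coordinates
(default 32 lines on a 512-px field → 16 px gauge, width 3 px, offset
half a gauge), per-frame Brownian motion (default σ = 1 px), Gaussian
read noise (default σ = 15, i.e. SNR ≈ 10 at the median baseline) and
optional Poisson shot noise. Placement is rejection sampling with a
minimum spacing that includes a 4-sigma allowance for the *relative*
Brownian drift of a nucleus pair over the acquisition.

Per-nucleus kinetics: DDR
`MS(t) = Amp · (1 − e^(−t/τ_r)) e^(−t/τ_d)` rescaled so the continuous
maximum equals Amp (Amp ∈ [0.5, 1.5], τ_r ∈ [3, 8] min, τ_d ∈ [40, 80]
min, giving peak times around 10–20 min); FRAP
`MS(t) = Amp · e^(−t/τ_rec)` with Amp ∈ [−0.7, −0.4], τ_rec ∈ [20, 40]
min; CONST holds MS fixed (used to demonstrate the frozen-fit decay).
Frames at *t* < 0 are rendered homogeneous, so FRAP scenes include one
pre-bleach frame for segmentation.

The stripe modulation is constructed analytically: per nucleus and
frame, stripe and inter-stripe pixels are scaled so the MS realised on
the ground-truth mask equals the programmed value exactly — conserving
total SID in DDR/CONST modes (recruitment redistributes signal) and
removing signal from the stripes only in FRAP mode. This makes the
generator its own oracle: on a noiseless, motionless scene the full
pipeline must reproduce MS_true to machine precision, and it does
(< 1e−12 observed, tested at 1e−3).

What the generator does not emulate: optics (no PSF beyond the hard
nucleus edge), intra-nuclear texture, nucleoli, photobleaching during
acquisition, cell division, touching nuclei, and shape change over
time. Passing tests therefore demonstrate the correctness of the
algorithmic chain under the model's assumptions, not robustness to
every property of real micrographs; the segmentation and fit gates are
configurable precisely because real data will need them retuned.

One residual fragility is worth knowing: at weak stripe contrast
(|MS| below roughly 0.25) combined with read noise, the angular
response of small nuclei is nearly flat and the orientation estimate
occasionally lands 10–15° off, producing an outlier MS record (about
one per few hundred records at SNR 10). Median-based curve parameters
and group statistics absorb these; single-record readouts should not
rely on frames near the baseline.

## Problem sizes and tolerances in the validation suite

End-to-end closure uses 20 nuclei × 10 frames (512² noiseless — max
error observed at machine precision, asserted < 1e−3; 640² with σ = 3
px/frame motion and read noise at SNR ≥ 10 for every nucleus — asserted
< 0.1). Kinetic-parameter recovery uses 200 nuclei across 10 seeded
scenes sampled every 5 min (median Amp within 10%, median Tpeak within
one frame interval). The fit is checked against an independently coded
exhaustive search on 50 random 64² instances (exact agreement), the
type-I error of the Kruskal–Wallis path over 1000 null simulations
(0.05 ± 0.02), and tracking identity on Brownian scenes with steps at
less than half the search radius (exact bijection). The noisy-closure
scene sets read noise to one tenth of the *dimmest* baseline; with
noise tied to the median baseline instead, the dimmest nuclei sit at
SNR ≈ 3 where their measurement noise alone exceeds the 0.1 band.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `width_px` | 3 px | stripe width (hardware constant, not fitted) |
| `d_range` | [0.5, 1.5] × D_nominal | integer gauges searched |
| `p_window` | D_nominal/2 | offset search window around the anchor column |
| `search_radius_px` | 25 px | tracking vicinity at 40× |
| `max_carry` | 2 frames | rigid carry-forward before a track is lost |
| `smoothing_sigma_px` | 1 px | pre-threshold smoothing (0 = raw) |
| `fit_smoothing_sigma_px` | 2 px | along-stripe smoothing for the fit only |
| `alpha` | 0.05 | significance level of all tests |
| `min_cells` | 100 | minimum group size for comparisons |
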