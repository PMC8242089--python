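# Methods

This note describes the models and estimators implemented in `foceamap`, in
the order a typical analysis uses them.

## Spherical geometry and r-eccentricity

Visual directions are expressed in a head-centered spherical frame: azimuth
is the angle about the vertical axis, elevation the angle above the horizon.
The *focea* is the reference direction (azimuth 0°, elevation +20°). The
angular distance of a receptive field (RF) from the focea along the visual
sphere, accounting for the convergence of azimuth lines away from the
horizon, is the tangent-composed *r-eccentricity*

```
r_ecc = arctan( sqrt( tan²(Δa) + tan²(Δe) / cos²(Δa) ) )
```

for offsets (Δa, Δe) from the focea. This equals
`arccos(cos Δa · cos Δe)`, the great-circle distance between the two
directions when the offsets are applied as successive rotations; it is
defined for |Δa|, |Δe| < 90°. The inverse mapping
(`ecc_offsets_from_polar`) places a point at exact r-eccentricity `e` in
polar direction φ, so simulations can round-trip the metric exactly.

Gaussian RF sizes are reported as full width at half maximum,
`FWHM = 2·sqrt(2·ln 2)·σ ≈ 2.3548·σ`.

Stimulus positions on a flat screen map to angles through
`azi = arctan(x/d)`, `ele = arctan(y / sqrt(d² + x²))` for a screen at
distance `d`.

## Stimuli

Retinotopy uses sets of bar apertures (default 20° wide) that tile the
stimulated field at one or more orientations; the signed distance of a grid
point from a bar's center line is `A·cos θ − E·sin θ`, so orientation 0 is a
vertical bar tiling the azimuth axis. Sparse-noise
sequences place multiple checks per frame with per-position presentation
counts balanced to within one; a "two-photon" dialect additionally forbids
adjacent checks within a frame. Session duration is
`n_stimuli · n_reps · (stim + isi)`.

## Wide-field pRF mapping

Frames are 2×2 mean-pooled and smoothed with a 7×7 moving mean. The evoked
response per stimulus is the fractional fluorescence change
`(F − F0)/F0` between a post-onset response window and a pre-onset baseline,
averaged over presentations. Each pixel is fit by exhaustive search over a
dictionary of 2D Gaussian candidate pRFs (centers on a 2° lattice inside the
stimulated region, FWHM 20–120° in 2° steps): for each entry the optimal
positive gain has a closed form, and the winner minimizes the residual sum
of squares; ties resolve to the smaller, more foceal Gaussian. Every
`stride`-th pixel is fit and the rest interpolated linearly. Pixels whose
model-data Pearson correlation falls below threshold are discarded.

pRF size versus r-eccentricity is fit as `FWHM = G·r_ecc + c` with weights
`1/max(r_ecc, 0.5°)`, emphasizing the foceal region; optionally the foceal
direction itself is a free parameter found by grid search plus joint
refinement.

## Field sign and segmentation

The field sign is `sin(θ_ele − θ_azi)` of the Sobel-gradient directions of
the smoothed elevation and azimuth maps (image y-axis inverted). Mirror-image
areas take one sign and adjacent non-mirror areas the opposite. The
continuous map is smoothed, thresholded three-ways at ±t, cleaned by
morphological opening and closing, and segmented into connected components;
V1 is the largest negative-sign region. Maps from multiple animals are
averaged after translating each to its V1 centroid and rescaling by the V1
major/minor axis lengths.

## Single-unit receptive fields

Per-position mean responses from sparse-noise trials form an RF map
(optionally with a running-speed nuisance regressor partialled out in a
joint linear model). The map is fit with a circular or elliptical 2D
Gaussian by bounded nonlinear least squares from multiple starts. Units are
screened by fit r² > 0.33, positive amplitude, and a bootstrapped
variability index — the pooled SD of bootstrap-resampled RF-center estimates
divided by the fitted σ — below 1.

## Cortical magnification and RF scatter

The cortical foceal point is the 100-µm-radius window (on a 25-µm lattice)
whose cells' mean r-eccentricity is minimal. Cortical axes are rotated so
the azimuth gradient lies along x. Along a chosen axis, cortical position
`x` versus visual coordinate `v` is modeled as `v = a·xᵇ` and fit by
minimizing the sum of absolute residuals (Nelder–Mead on (log a, b), seeded
by a log-log least-squares fit); visual variables spanning non-positive
values are shifted by `−min + 1` first. Cortical magnification (mm/deg) is
evaluated by forward differences of the inverse model over 5° steps; the
foceal magnification is the value at the evaluation midpoint nearest the
focea.

RF scatter is measured from the fit residuals (observed minus fitted visual
position, in degrees). Cells are split into ten equal-count bins *ordered by
their fitted value* — a function of the noise-free cortical position, so the
ranking is not contaminated by the scatter being measured — while each bin's
abscissa is its mean *observed* value. The interquartile range of residuals
per bin is regressed on the bin centers; dividing the slope by 1.349 (the
IQR of a unit Gaussian) converts it to a σ-per-degree coefficient. A
permutation null (residuals shuffled across cells) yields a one-tailed
p-value for the slope. A separate two-group permutation test compares
residual SD between binocular (|azimuth| < 15°) and monocular RFs.

Aggregate pRFs summarize all units within a cortical window: each unit
contributes a disc of diameter FWHM at its RF center, and the aggregate
area is the convex hull of the disc union, with diameter `2·sqrt(area/π)`.
Aggregate diameter is regressed on r-eccentricity with unit-count covariates
(n, √n). A raw-pixel variant stitches overlapping tile maps (averaging
overlaps, linearly interpolating interior gaps, rejecting disconnected
coverage) and slides windows over the stitched canvas, keeping windows with
at least 75% observed data.

## Synthetic cortex models

The conceptual V1 model places cells on an `n×n` grid spanning 2.4 mm.
Model A maps cortical radius `z` to eccentricity `(1/0.02)·zᵃ` — linear at
magnification 0.02 mm/deg when `a = 1`, compressive for `a > 1`. Model B
adds radial RF scatter: eccentricity is redrawn from a Gaussian centered on
the noise-free value with SD `k·ecc`, folded to stay positive. The polar
angle is preserved; offsets use either a planar decomposition or the exact
spherical inverse. These generators drive all parameter-recovery tests.

## Psychophysics

Sensitivity is `d′ = Z(hit rate) − Z(false-alarm rate)` with extreme rates
corrected to `1/(2N)` or `1 − 1/(2N)`. Hit rates as a function of spatial
frequency are modeled as

```
P(hit | sf) = γ + (1 − γ − λ) / (1 + exp(β·(sf − α)))
```

with the guess rate γ fixed at the session's false-alarm rate, a shared
lapse λ, shared slope β, and per-location inflexion α (the threshold). The
"restricted" model shares α across locations. Fits maximize the binomial
likelihood from multiple starts; flat data are flagged unidentifiable.
Location dependence is tested by `LR = −2·(ll_restricted − ll_full)` against
χ² with 1 degree of freedom (or `n_locations − 1` on request).

## Gaze and optic flow

Eye sockets are modeled with optic axes at ±60° azimuth and +30° elevation;
the focea-in-eye vector is obtained by inverting the eye rotation at the
reference (mean head-fixed) eye position, so the reference state projects
exactly to (0°, +20°). Head orientation applies roll about the x-axis then
pitch about y; eye torsion follows pitch linearly with gain 0.325. The
*foceal projection* for arbitrary eye angles and head tilt is the world
direction of this vector; compensatory eye positions that re-aim it at the
focea are solved per sample (with torsion slaved to pitch the solution is
exact at moderate pitch and within ~1° at ±45–60°). Projection directions
are accumulated in spherical histograms summarized by circular mean and SD;
conditions are compared after stratified subsampling that equalizes joint
pitch/roll histograms. Periods of straight locomotion are intervals with
body speed above 10 cm/s and head-body velocity difference below 1 cm/s.

The experiment chamber is a symmetric trapezoid (wide wall 24 cm at the
screen, narrow wall 6 cm, length 18 cm, height 20 cm). Optic flow is
computed by casting grid directions around the mean foceal projection as
rays from the eye, intersecting them with the chamber walls, and measuring
the angular displacement of the wall points between successive eye
positions; flows are circular-averaged across frame pairs. At rest the flow
is identically zero; during forward locomotion it radiates from the focus
of expansion.
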