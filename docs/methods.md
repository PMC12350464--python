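# Methods

## Image formation and the photometric depth model

The pipeline assumes endoscopic imaging with the light source at the camera
centre. Its working model is the illumination-decline law

    I = clip(gain · ρ · s / d², 0, 1)^(1/γ)

with d the Euclidean distance from the optical centre to the surface *along
the viewing ray* (not z-depth — the inverse-square law governs physical
distance from the source), ρ the surface albedo, γ the sensor gamma and s a
shading factor. The analytic depth estimator inverts this with ρ ≡ 1 and
s ≡ 1:

    d̂ = I_norm^(−γ/2),   I_norm = gray / 255

which recovers depth up to one global scale wherever the pure decline model
holds. Pixels at or below a noise floor (default 0.02 ≈ 5/255) carry no
reliable photometric signal and are masked, as are saturated pixels
(≥ 250), which are treated as specular. The phantom renderer uses the same
law with s ≡ 1 by default; a Lambertian factor s = max(n·l, 0) is available
(`RenderConfig.shading="lambertian"`) for robustness experiments. The two
choices are deliberately asymmetric in difficulty: under Lambertian shading
the pure inversion distorts depth nonlinearly (for a cylinder I^γ ∝ R/d³,
so d̂ ∝ d^{3/2}), which is precisely the regime where a learned estimator —
pluggable through `register_estimator` — is needed. The analytic default
documents what geometry alone can do.

Backprojection places each valid pixel at d̂ times its *unit* ray through
the pinhole intrinsics (0-based pixel-centre convention). Normals come from
the cross product of finite-difference tangents of the backprojected grid,
oriented to face the camera. No depth smoothing is applied by default; a
radius-1 median filter is available behind a flag for noisy inputs.

## Segmentation, tracking, keyframe

Dark-region segmentation thresholds raw grayscale luma (BT.601) at
intensity 50 — a value validated on real endoscopy by visual assessment —
and keeps the largest 8-connected component covering at least 0.1% of the
frame. Components touching the border are eligible (the lumen often does
during approach). The tracker compares each frame's largest dark segment
with the last successfully tracked mask: IoU ≥ 0.5 updates the reference,
otherwise a miss counter runs (the reference is not updated on misses,
preserving robustness to transient illumination changes); after 25
consecutive misses the track is declared lost. The keyframe is the *first*
frame of the terminal miss run: that is the frame where the darkest segment
first changed for good, i.e. where the camera has just entered the
subglottis; waiting out the patience window would select a frame 25 frames
too late.

## Cross-sections and indices

The stenosis contour is the set of cloud points whose pixels form the
morphological outer edge (dilation minus mask) of the dark region: those
pixels lie just outside the aperture, on tissue with reliable depth. Masks
smaller than 3 pixels are rejected. A total-least-squares plane is fitted
to the contour (smallest principal direction; degenerate/collinear input is
an error), and the stenosed section is the convex hull of the points of the
segmented region (mask plus rim) within a slab around that plane. The slab
half-width is the larger of 2% of the cloud's median depth (a scale-free
default) and twice the contour's RMS scatter about its own plane — the
photometric noise spreads the rim along the viewing rays, and a slab much
thinner than that spread would miss the very points that delineate the
section. Restricting the stenosed slab to the segmented region matters: the
funnel-shaped wall around the aperture enters a whole-cloud slab with
noise-displaced points at larger radii, and a convex hull latches onto such
outliers.

The reference sweep intersects camera-perpendicular planes at 50 evenly
spaced depths between the 5th percentile of cloud depth and the stenosis
plane's mean depth, keeping the spec of each section as the full-cloud slab
(2% of median depth); the maximal area wins, ties resolving to the plane
nearest the camera (deterministic, and the proximal section is least
occluded). Section areas are shoelace areas of the convex hull of the
in-plane projected slab points; circles are fitted to the hull vertices by
the algebraic least-squares (Kåsa) method — exact on exact circles, the
circumcircle for three points — with a `circle_fit_poor` flag when the RMS
residual exceeds 10% of the radius. Sections with fewer than 50 slab points
are flagged `sparse_section`.

PSA and PSD are reported unclamped; negative values (reference smaller than
stenosis) are flagged `reference_smaller_than_stenosis`, never clipped.
Because both indices are ratios within one cloud, they are exactly
invariant to the global depth-scale ambiguity; this is asserted to 1e-6
points in the validation suite.

## The synthetic phantom

The phantom emulates what the pipeline needs from a real SGS exploration:
a tubular airway (surface of revolution around a straight axis, camera
travelling on-axis), a vocal-cord aperture, a stenotic narrowing beyond it,
inverse-square illumination with gamma encoding, sensor noise, optional
specular highlights, and 8-bit quantization. Defaults (millimetres):
tracheal/subglottic radius 10, supraglottic (proximal) radius 8 blending at
the cords over a tanh ramp, vocal cords at z = 30, stenosis dip at z = 60
with Gaussian width σ = 1.5, tube length 150, albedo 0.8, γ = 2.2, noise
σ = 0.01 on the [0,1] intensity scale, gain resolved so the median wall
pixel at the start pose renders near 0.5 (keeping both the dark-threshold
and non-saturated regimes present). Rays that leave the far end render at
the 5/255 noise floor.

Two design choices deserve explanation because the paper-level phenomenon —
an *abrupt* change of the darkest segment exactly when the scope passes the
cords — does not arise from smooth concentric geometry: a smoothly evolving
blob is followed by any IoU tracker that updates its reference. The phantom
therefore models the cords as a thin diaphragm whose circular aperture
(radius 3.75) is offset 4.4 mm from the axis, as the real glottic opening
is offset from the tracheal axis: the diaphragm face occludes the image
centre until the moment of passage, after which the concentric stenosis
aperture appears at the centre — a genuine discontinuity at the crossing
frame. Second, the default trajectory advances slowly (≈0.4 mm/frame),
crosses the glottis with one brisk push (from 5.5 mm before to 0.5 mm past
the cord plane between two consecutive frames, emulating the quick push
physicians use to pass the cords), and continues slowly, stopping 10 mm
short of the stenosis — the stenosed region is never traversed. The
narrower proximal segment keeps the distal chamber dark relative to the
gain-derived threshold distance during the approach, so the tracker holds
the through-aperture segment right up to the push. A concentric
(offset-free) cord model remains available and is used by the geometry
unit tests.

Ground truth per sequence: true depth maps, lumen masks, the transition
index (first pose past the cord plane), the stenosis radius and the widest
open radius between cords and stenosis (what the reference sweep should
recover).

What the phantom does *not* model: tissue texture and albedo variation,
vocal-cord anatomy and motion, breathing deformation, curved centerlines,
secretions, tracheal cartilage rings (the subglottis has none), rolling
shutter. Passing tests on phantoms therefore validate the geometry and
photometry of the pipeline — segmentation, tracking logic, inversion,
sectioning, indices — not robustness to real-tissue appearance; that is
the role of the learned-estimator plug-in and clinical data.

## Validation experiments and problem sizes

`scripts/acceptance.py` (and the mirror tests in `tests/test_acceptance.py`)
run: (1) index recovery — 12 phantoms, stenosis/reference ratios
{0.3, 0.5, 0.7} × 4 seeds, full pipeline on 90-frame 320×256 sequences,
PSA/PSD within 5 points of the analytic circular-section values; (2)
keyframe recovery — 20 seeded 90-frame 160×128 sequences, keyframe within
[T−2, T+25] of the true transition T in ≥95%; (3) photometric round trip —
noise-free 8-bit render inverted, Pearson r > 0.99 against true depth; (4)
scale invariance — cloud scaled by 0.1/1/10, indices move < 1e-6; (5)
oracle equivalence — IoU, shoelace hull area, Kåsa circle fit and MAE
against brute-force/independent implementations on 100 random instances
each; (6) the same-patient consistency arithmetic recomputed exactly from
per-sequence estimates. The two camera sizes are fidelity choices per
experiment: measurement accuracy is pixel-limited at the aperture rim
(one-pixel outer-edge bias, the dominant, always-negative error — the
method slightly underestimates the index), while the threshold tracker is
resolution-insensitive.

## Numerical notes and limitations

- The dark threshold (50) is fixed in intensity, so index invariance under
  global intensity rescaling holds only while the rescaling does not move
  the segmentation boundary off the aperture rim; brightening by ~5%
  changes the indices by < 0.5 points, while strong dimming floods the mask
  past the rim and is not a valid operating regime.
- Sections are convex hulls; strongly concave (e.g. slit-like) stenoses
  would be over-measured. An alpha-shape variant is a possible extension.
- Ray casting marches a shared z grid (step σ/3) with per-ray bisection;
  features narrower than the grid step would be missed, so very sharp
  narrowings need a smaller `z_step`.
- The reference location follows this pipeline's definition — the widest
  section between the cords and the stenosis — which differs from the
  Myer–Cotton convention of a tracheal reference distal to the stenosis;
  grades are not directly comparable and no grade assignment is attempted.
- Metric (millimetre) scale is never recovered; all areas and diameters are
  in up-to-scale units and only the ratio indices are meaningful.
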