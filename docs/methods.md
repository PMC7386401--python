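# Methods

## Optical model and decision rules

The exam reduces two photographs to a handful of geometric quantities.

**Alignment (automated Hirschberg test).** The specular reflection of a
point flash sits, to first order, at the corneal point whose surface
normal bisects the flash–eye–camera geometry; with the flash next to the
camera and the examinee at arm's length, the offset of that spot from the
limbus center is proportional to the tangent of the eye's deviation from
the camera axis. Working in pixels with a frontal-plane scale α (mm/px)
and an eyeball diameter d (mm):

    θ_axis = tan⁻¹(2 α Δ_axis / d)   per eye and axis,

with Δ the CLR-minus-limbus offset (x right, y down). d is not measurable
in a photo and is fixed at the population average of 20 mm; the resulting
scale error on θ is common to both eyes and largely cancels in the
binocular differences θ_h, θ_v actually used for screening. Sign
semantics: positive θ_h (left minus right) → exotropia, negative →
esotropia, |θ_v| > 0 → vertical misalignment.

**Refraction (eccentric photorefraction).** Defocused fundus reflection
returns through the pupil as a bright crescent whose side (relative to the
flash) separates myopia from hyperopia and whose width grows with the
error magnitude. The width–diopter relation is device-specific and is not
modeled; the width in mm is reported as a severity *reference* only, and
the screening decision is purely the ≥ 1 mm cutoff. Both severe myopia
and severe hyperopia flood the whole pupil, so a fully lit pupil sets the
direction to "indeterminate" (still screening-positive).

**Decision rules.** Strabismus risk: max(|θ_h|, |θ_v|) ≥ 10°. The
combination rule across axes is a design choice (the cutoff is stated per
relative visual angle, not per axis); taking the max flags either axis
deviating. Refractive risk: per-eye crescent width ≥ 1 mm. Anisometropia:
unsigned |width_L − width_R| ≥ 1 mm; opposite-side crescents additionally
get a quality note. All comparisons are inclusive ("at least"). All
thresholds live in `ScreeningConfig` (YAML-loadable).

## Image-processing chain

Processing order is fixed: the Hirschberg still first (its contracted
pupil and subdued fundus reflection give the cleanest limbus), then the
red-reflex frame reusing the found radius.

1. **Landmarks and gating** (`localize`). Landmark detection itself is an
   external concern; records arrive as JSON (per-eye corners, ≥3 points
   per lid, head tilt). Eye openness = max vertical lid gap / corner
   distance; an eye is closed strictly below η = 0.25 (a ratio of exactly
   η passes, reading the cutoff as "below the threshold"). The image is
   rotated by −tilt about the midpoint of the eye-corner centroids
   (bilinear), and per-eye patches are cropped with 25% corner-distance
   padding per side. Anatomical labels: the examinee's left eye is on the
   image's right half.
2. **Skin-masked ROI** (`build_roi_mask`). Skin is modeled by the median
   hue (circular) and saturation of the patch's outer 10% border frame;
   pixels within ±10° hue and ±0.12 saturation are skin. The ROI is the
   connected non-skin component containing the patch center. Medians
   rather than means keep the model on the skin when another structure
   clips the border. Hue/saturation (not value) are used, so very dark
   *chromatic* iris colors can fall inside the skin tolerance — with the
   target population's near-black, low-chroma irises this does not arise,
   and the synthetic palette reflects that.
3. **IsoData threshold** (`isodata_threshold`). Intermeans fixed point
   t ← floor((mean≤t + mean>t)/2), initialized at the floor midpoint of
   the occupied range. The floor makes the update monotone on integer
   levels, guaranteeing termination at a true fixed point; half-up
   rounding can 2-cycle between adjacent occupied bins.
4. **Arc-restricted Hough** (`detect_limbus_hirschberg`). Edge points are
   the boundary pixels of the sub-threshold (dark) region. Each point
   votes, for every radius in [0.15, 0.45] × corner distance (1 px
   steps), only for centers from which the point lies within ±45° of
   horizontal — the left/right limbus arcs — so eyelid-covered arcs are
   never required and contribute no votes. Scores are 3×3-summed vote
   masses; ties break toward more votes, larger radius, smaller y,
   smaller x. Sub-pixel refinement: vote-mass centroid (5×5) for the
   center, parabolic fit over adjacent radii plus a +0.5 px rim offset
   (edge pixels are centers of the outermost dark pixels) for the radius.
   Peak support below 20 points raises a detection failure.
5. **Contrast refinement** (`refine_limbus_photorefraction`). In the
   red-reflex frame the radius is held to the prior (±10% searched) and
   the center maximizes mean(outer annulus r..1.15r) − mean(inner annulus
   0.85r..r), annuli restricted to the same ±45° arcs, on a ±6 px integer
   grid with separable parabolic sub-pixel refinement. Non-positive best
   contrast raises a detection failure.
6. **CLR spot** (`detect_clr`). Candidates inside the limbus disk whose
   min-channel intensity reaches the disk maximum within 2% of the
   dynamic range; largest 4-connected component (ties: topmost-then-
   leftmost centroid); inscribed circle at the distance-transform
   maximum, with the center refined to the centroid of the near-maximal
   plateau (sub-pixel, symmetric).
7. **Crescent** (`detect_crescent`). Inside the limbus disk, excluding
   the CLR component padded by 3 px (saturated halo pixels must not
   masquerade as crescent), pixels pass with (R > G + B AND brightness >
   2 × median disk brightness) OR saturated red; brightness is (R+G+B)/3;
   the median excludes the CLR exclusion zone. Components under 5 px are
   dropped (8-connectivity: a thin crescent arc fragments under
   4-connectivity). Width = α × horizontal extent of the retained set —
   the flash-displacement axis; whether the "oval width" means an ellipse
   axis is unstated, and the horizontal extent is the axis the optics
   displaces the crescent along. The measurement runs on a 2× bilinear
   supersample of the patch (the 0.1 mm recovery target is below the
   native pixel pitch at typical scales), and the extent is the integral
   of per-column coverage: the red-dominance score R − G − B is linear in
   a blended pixel's crescent fraction, so each column's peak score,
   normalized between the local background and the crescent plateau,
   estimates its fractional coverage sub-pixel. Side: retained-set
   centroid vs limbus center under the
   configured flash geometry. Retained area ≥ 70% of the limbus disk sets
   `full_pupil` and reports the limbus diameter as width. An empty set is
   a valid zero-width crescent, not an error.
8. **Scale** (`decode_scale`, `qr`). The QR payload is JSON
   `{"id", "edge_mm"}`; α = edge_mm / mean of the four decoded corner-
   quadrilateral side lengths. The in-house coder implements ISO/IEC
   18004 byte mode, versions 1–5, EC level L, mask 0, with GF(256)
   Reed–Solomon (single-symbol error correction on decode). The reader
   assumes an upright frontal symbol — the protocol holds the phone flat
   against the forehead — and finds finder patterns by 1:1:3:1:1
   run-length scanning with support- and module-size-consistency
   filtering; exactly one symbol must be present.
9. **IPD**: α × distance between the two Hirschberg limbus centers in
   tilt-corrected coordinates.

## Synthetic scenes: what they emulate, and what they do not

`synthgen` renders flat-shaded analytic scenes: skin background, an
elliptical palpebral fissure (semi-axes 2.0 R × 1.3 R), iris disk of
limbus radius R, pupil (contracted to 50% in the flash still), a white CLR
disk (8% of R) at the specified offset, a red crescent rendered as the
pupil cut by a vertical line so its horizontal width is exact, skin-
colored lid overlays covering the top/bottom limbus arcs beyond the
occlusion half-angle, an upright QR fiducial at the forehead, head tilt
applied analytically (each pixel is evaluated through the exact inverse
rotation — no resampling touches the ground truth), and per-channel
additive Gaussian noise clipped to [0, 255] under a single seed. A reflex
covering more than half the pupil is drawn with a saturated red channel,
as an intense fundus glow overexposes the sensor.

Ground truth contains the exact scale, offsets, closed-form angles
(computed by the same `screen` closed form, so generator and classifier
cannot drift apart), widths, sides, landmark record and condition labels
obtained by thresholding the noise-free truth with the classifier itself.

Default study conditions (the cohort generator): 1024×704 px frames at
9.2–10.2 px/mm; IPD 54–60 mm; limbus radius 5.2–5.9 mm; dilated pupil
0.55–0.68 R; head tilt ±8°; lid occlusion 0–25°; affected deviations
13–18° (70% horizontal), unaffected ≤ 3°; affected crescent widths
1.4–2.6 mm toward the flash; unaffected eyes show either no crescent
(refractive error below the reflex threshold produces none) or a mild,
optically formed one of 0.25–0.5 mm — never a sub-resolution sliver,
which the minimum-component rule would rightly reject; width
configurations are kept clear of the 1 mm cutoffs so truth labels are
stable under sub-0.1 mm measurement error; prevalences 0.20 (strabismus), 0.30
(examinee-level myopia), 0.10 (anisometropia — realized as a unilateral
or strongly asymmetric crescent, whose wider eye is then necessarily
myopic); 13% of examinees blink on the first attempt, producing a
closed-eye pair plus an open retake.

Not emulated: photorealistic shading, corneal curvature and perspective,
fundus reflectance physics, gaze-dependent iris deformation, motion blur,
video, colored contact lenses (a known failure mode of limbus detection),
or landmark-detector error (synthetic records are exact). Passing tests
therefore demonstrate the correctness and numerical behavior of the
measurement chain under controlled geometry and noise — not clinical
performance on real photographs.

## Numerical choices and degenerate inputs

- Coordinates are 0-based, x right / y down, pixel centers on integers;
  positive rotation is counterclockwise on screen.
- Khachiyan's MVEE iteration stops at a KKT gap of 1e-6 and rescales the
  shape matrix so the farthest point lies exactly on the boundary;
  single-point and collinear inputs get a tiny regularization and return
  valid (thin) ellipses.
- Hough determinism: fixed tie-break order, integer grids, no randomness
  anywhere in the pipeline; rendering and batch outputs are pure
  functions of (spec, seed), and reports serialize with sorted keys so
  reruns are byte-identical.
- Degenerate guards: < 2 occupied histogram bins, all-skin patches, empty
  candidate sets, zero corner distance, coincident limbus centers,
  undecodable or multiple QR symbols, and zero metric denominators each
  raise a typed error naming the stage; an empty crescent is data, not an
  error.
- Problem sizes in the test suite (200 random scenes for recovery, 40 for
  heavy occlusion, 100-examinee cohorts, 1000 histograms / 100 components
  / 100 point sets for the oracles) were chosen to exercise the stated
  bounds with comfortable sampling margins while keeping a full run on a
  single CPU in the minutes range.

## Known limitations

- The d = 20 mm eyeball assumption biases per-eye angles for eyes far
  from that diameter; only the binocular differences are thresholded.
- Hidden (intermittent) strabismus is invisible to a single flash photo
  by construction; a cover test remains the referral standard.
- The ±10° rule on max(|θ_h|, |θ_v|) is one reading of an axis-ambiguous
  cutoff; the per-axis angles are all reported for downstream use.
- The QR reader does not handle perspective-distorted or rotated symbols.
- Crescent width in mm is not a diopter estimate; calibration to
  refractive power is device-specific and out of scope.
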