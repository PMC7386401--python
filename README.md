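# photoscreen

Automated analysis for smartphone-based pediatric vision screening.

A low-cost screening exam photographs a child's face twice with an
eccentric flash: once with contracted pupils (an automated **Hirschberg
test**, reading ocular alignment from the corneal light reflection) and
once with dilated pupils (eccentric **photorefraction**, reading refractive
error from the red-reflex crescent in the pupil). A QR code of known
physical size, shown on a phone held at the child's forehead, calibrates
the frontal-plane scale. From these two images plus a facial-landmark
record, this package measures binocular axis deviation, per-eye red-reflex
crescent widths and interpupillary distance, and flags the risk of
strabismus, myopia and anisometropia. It is aimed at screening programs in
resource-limited settings, where the examiner is a teacher or nurse with a
phone rather than an optometrist with a clinical photoscreener.

## Model

With the corneal-light-reflection (CLR) spot offset from the limbus center
by `(Δx, Δy)` pixels, a frontal-plane scale of `α` mm/px and an assumed
eyeball diameter `d = 20` mm, the axial deviation of one eye per axis is

    θ = tan⁻¹(2 α Δ / d)

The binocular deviations are the left-minus-right differences
`θ_h = θ_h,L − θ_h,R` (positive → exotropia, negative → esotropia) and
`θ_v` likewise (nonzero → vertical strabismus). A crescent on the flash
side of the pupil indicates myopia, on the far side hyperopia; a fully lit
pupil leaves the direction indeterminate. Screening cutoffs: deviation
≥ 10° on either axis, crescent width ≥ 1 mm, inter-eye width difference
≥ 1 mm.

The image operators are deliberately classical and deterministic: IsoData
(intermeans) thresholding splits sclera from iris; an **arc-restricted
circle Hough transform** finds the limbus from edge points on the left and
right ±45° arcs only, so eyelid-covered top/bottom arcs never vote; the
red-reflex frame reuses the Hirschberg radius and relocates the limbus by
maximizing annulus contrast; the CLR spot is the maximal-intensity cluster
with an inscribed circle; crescent pixels pass a red-dominance plus
brightness filter and get a minimum-area enclosing ellipse (Khachiyan) and
a horizontal-extent width. A built-in synthetic eye-scene renderer
(`photoscreen.synthgen`) produces both exam frames with exact ground truth
— geometry, offsets, widths, landmarks, condition labels — so the whole
pipeline is testable without clinical data.

## Worked example

```bash
photoscreen simulate cohort_out --n 1 --seed 4
photoscreen exam cohort_out/S0000_a0_hirschberg.png \
    cohort_out/S0000_a0_redreflex.png \
    cohort_out/S0000_a0_landmarks.json --examinee-id S0000
```

prints (abridged; the full report also carries a per-stage trace):

```json
{
 "examinee_id": "S0000",
 "gaze_deg": {"horizontal": -2.407, "vertical": 0.167, ...},
 "crescent_width_left_mm": 0.0,
 "crescent_width_right_mm": 0.536,
 "crescent_side_right": "toward-flash",
 "ipd_mm": 57.032,
 "flags": {"strabismus": false, "refractive_left": false,
           "refractive_right": false, "anisometropia": false}
}
```

This child's binocular deviation is −2.4° horizontally (mild, well under
the 10° cutoff; the negative sign would indicate esotropia were it
large), the right eye shows a faint 0.54 mm flash-side crescent (under
the 1 mm refractive cutoff), the inter-eye width difference is under
1 mm, and the recovered IPD is 57.0 mm — every flag negative. The same library
calls are available programmatically via `photoscreen.run_exam` /
`photoscreen.pipeline.analyze_images`, and `photoscreen batch` +
`photoscreen evaluate` score whole manifests against truth labels.

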