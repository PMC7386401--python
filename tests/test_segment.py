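"""Image operators against ground truth and independent oracles."""

import dataclasses
import math

import numpy as np
import pytest

from photoscreen import screen, segment, synthgen
from photoscreen.errors import DetectionError

from conftest import make_scene, measure_eye


# ----------------------------------------------------------------------------
# IsoData
# ----------------------------------------------------------------------------

def isodata_update(hist, t):
    """One step of the intermeans map, written independently."""
    levels = list(range(256))
    lo = [(l, c) for l, c in zip(levels, hist) if l <= t and c > 0]
    hi = [(l, c) for l, c in zip(levels, hist) if l > t and c > 0]
    if not lo or not hi:
        return None
    mean_lo = sum(l * c for l, c in lo) / sum(c for _, c in lo)
    mean_hi = sum(l * c for l, c in hi) / sum(c for _, c in hi)
    return math.floor((mean_lo + mean_hi) / 2.0)


class TestIsoData:
    def test_two_spikes(self):
        hist = np.zeros(256, dtype=int)
        hist[50] = 100
        hist[200] = 100
        assert segment.isodata_threshold(hist) == 125

    def test_uniform(self):
        t = segment.isodata_threshold(np.ones(256, dtype=int))
        assert t in (127, 128)

    def test_single_bin_error(self):
        hist = np.zeros(256, dtype=int)
        hist[77] = 10
        with pytest.raises(DetectionError):
            segment.isodata_threshold(hist)

    def test_fixed_point_on_random_histograms(self):
        """The returned level is a fixed point of the intermeans map and
        matches an independently simulated iteration, on 1,000 histograms."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            kind = rng.integers(3)
            if kind == 0:
                hist = rng.integers(0, 50, size=256)
            elif kind == 1:  # bimodal
                hist = np.zeros(256, dtype=int)
                for mu, s, n in ((rng.integers(10, 100), 8, 400),
                                 (rng.integers(150, 245), 12, 500)):
                    vals = np.clip(rng.normal(mu, s, n).round(), 0, 255)
                    hist += np.bincount(vals.astype(int), minlength=256)
            else:  # sparse spikes
                hist = np.zeros(256, dtype=int)
                for lev in rng.integers(0, 256, size=rng.integers(2, 6)):
                    hist[lev] += int(rng.integers(1, 100))
            if np.count_nonzero(hist) < 2:
                continue
            t = segment.isodata_threshold(hist)
            assert isodata_update(hist, t) == t, "not a fixed point"
            # independent simulation from the midpoint of the occupied range
            occ = np.flatnonzero(hist)
            cur = (int(occ[0]) + int(occ[-1])) // 2
            seen = set()
            while cur not in seen:
                seen.add(cur)
                nxt = isodata_update(hist, cur)
                if nxt is None:
                    cur += 1 if isodata_update(hist, cur + 1) is not None else -1
                    continue
                cur = nxt
            assert t == cur

    def test_agrees_with_skimage_reference(self):
        from skimage.filters import threshold_isodata

        rng = np.random.default_rng(1)
        hist = np.zeros(256, dtype=int)
        hist += np.bincount(np.clip(rng.normal(60, 10, 500).round(), 0, 255)
                            .astype(int), minlength=256)
        hist += np.bincount(np.clip(rng.normal(200, 10, 500).round(), 0, 255)
                            .astype(int), minlength=256)
        ours = segment.isodata_threshold(hist)
        ref = threshold_isodata(hist=(hist, np.arange(256)))
        assert abs(ours - ref) <= 1


# ----------------------------------------------------------------------------
# ROI mask
# ----------------------------------------------------------------------------

class TestRoiMask:
    def test_covers_eye_excludes_skin(self, scene_patches):
        spec = scene_patches["spec"]
        patch = scene_patches["h"]["left"]
        mask = segment.build_roi_mask(patch.pixels)
        # skin pixels are those equal to the flat skin color
        skin = np.all(patch.pixels == np.asarray(spec.skin_rgb), axis=-1)
        assert (mask & skin).sum() <= 0.01 * skin.sum()
        # the limbus disk itself must be inside the ROI
        truth = scene_patches["truth"]
        c = patch.from_corrected(truth.limbus_center_left)[0]
        yy, xx = np.mgrid[0:patch.pixels.shape[0], 0:patch.pixels.shape[1]]
        disk = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 \
            <= (0.9 * truth.limbus_radius_left) ** 2
        assert mask[disk].mean() > 0.99

    def test_all_skin_error(self):
        patch = np.full((50, 50, 3), (214, 160, 120), dtype=np.uint8)
        with pytest.raises(DetectionError):
            segment.build_roi_mask(patch)

    def test_idempotent(self, scene_patches):
        patch = scene_patches["h"]["right"]
        stats = segment.estimate_skin_stats(patch.pixels)
        m1 = segment.build_roi_mask(patch.pixels, stats)
        blanked = patch.pixels.copy()
        blanked[~m1] = 0  # mask out, then mask again with the same stats
        m2 = segment.build_roi_mask(blanked, stats)
        assert (m1 & m2).sum() / m1.sum() > 0.99


# ----------------------------------------------------------------------------
# Limbus detection (arc-restricted Hough)
# ----------------------------------------------------------------------------

class TestLimbusHirschberg:
    def test_clean_recovery(self, scene_patches):
        truth = scene_patches["truth"]
        for eye, tc, tr in (("left", truth.limbus_center_left,
                             truth.limbus_radius_left),
                            ("right", truth.limbus_center_right,
                             truth.limbus_radius_right)):
            m = measure_eye(scene_patches, eye)
            patch = scene_patches["h"][eye]
            c_true = patch.from_corrected(tc)[0]
            err = np.hypot(*(np.asarray(m["limbus"].center) - c_true))
            assert err <= 1.0
            assert abs(m["limbus"].radius - tr) / tr <= 0.02

    @pytest.mark.parametrize("occ", [30.0, 40.0])
    def test_occlusion_robustness(self, occ):
        """Top/bottom lid occlusion must not disturb the arc-restricted fit."""
        spec = make_scene()
        spec = dataclasses.replace(
            spec,
            left=dataclasses.replace(spec.left, lid_occlusion_deg=(occ, occ)),
            right=dataclasses.replace(spec.right, lid_occlusion_deg=(occ, occ)),
            embed_qr=False,
        )
        from photoscreen import localize

        img, _, truth = synthgen.render_exam(spec)
        lm = localize.load_landmarks(truth.landmarks)
        left, right = localize.extract_eye_patches(img, lm)
        for patch, tc, tr in ((left, truth.limbus_center_left,
                               truth.limbus_radius_left),
                              (right, truth.limbus_center_right,
                               truth.limbus_radius_right)):
            mask = segment.build_roi_mask(patch.pixels)
            limb = segment.detect_limbus_hirschberg(
                patch.pixels, mask, corner_distance=patch.corner_distance)
            c_true = patch.from_corrected(tc)[0]
            assert np.hypot(*(np.asarray(limb.center) - c_true)) <= 1.0
            assert abs(limb.radius - tr) / tr <= 0.02

    def test_blank_patch_fails(self):
        patch = np.zeros((80, 80, 3), dtype=np.uint8)
        with pytest.raises(DetectionError):
            segment.detect_limbus_hirschberg(
                patch, np.ones((80, 80), dtype=bool), corner_distance=100.0)

    def test_translation_equivariance(self, scene_patches):
        """Shifting the patch by integer (dx, dy) shifts the detections."""
        patch = scene_patches["h"]["left"]
        dx, dy = 4, -3
        shifted = np.roll(patch.pixels, (dy, dx), axis=(0, 1))
        mask0 = segment.build_roi_mask(patch.pixels)
        mask1 = np.roll(mask0, (dy, dx), axis=(0, 1))
        l0 = segment.detect_limbus_hirschberg(
            patch.pixels, mask0, corner_distance=patch.corner_distance)
        l1 = segment.detect_limbus_hirschberg(
            shifted, mask1, corner_distance=patch.corner_distance)
        np.testing.assert_allclose(
            np.asarray(l1.center) - np.asarray(l0.center), (dx, dy), atol=0.2)
        assert l1.radius == pytest.approx(l0.radius, abs=0.2)
        c0 = segment.detect_clr(patch.pixels, l0)
        c1 = segment.detect_clr(shifted, l1)
        np.testing.assert_allclose(
            np.asarray(c1.center) - np.asarray(c0.center), (dx, dy), atol=0.2)


class TestLimbusRefinement:
    def test_shifted_prior_recovered(self, scene_patches):
        truth = scene_patches["truth"]
        m = measure_eye(scene_patches, "left")
        patch_r = scene_patches["r"]["left"]
        c_true = patch_r.from_corrected(truth.limbus_center_left)[0]
        prior = segment.LimbusCircle(
            center=(m["limbus"].center[0] + 3, m["limbus"].center[1] - 3),
            radius=m["limbus"].radius, score=0.0, source="hirschberg")
        refined = segment.refine_limbus_photorefraction(patch_r.pixels, prior)
        assert np.hypot(*(np.asarray(refined.center) - c_true)) <= 1.0

    def test_uniform_patch_fails(self):
        patch = np.full((120, 120, 3), 100, dtype=np.uint8)
        prior = segment.LimbusCircle((60.0, 60.0), 30.0, 0.0, "hirschberg")
        with pytest.raises(DetectionError):
            segment.refine_limbus_photorefraction(patch, prior)

    def test_contrast_peak_against_exhaustive_scan(self, scene_patches):
        """The annulus contrast at the true center beats every center at
        least 5 px away (brute-force scan)."""
        truth = scene_patches["truth"]
        patch_r = scene_patches["r"]["left"]
        gray = segment._brightness(patch_r.pixels)
        c_true = patch_r.from_corrected(truth.limbus_center_left)[0]
        r = truth.limbus_radius_left
        xs = np.arange(int(c_true[0]) - 12, int(c_true[0]) + 13)
        ys = np.arange(int(c_true[1]) - 12, int(c_true[1]) + 13)
        centers = np.array([(x, y) for y in ys for x in xs], dtype=float)
        contrast = segment._annulus_contrast(gray, centers, r)
        at_truth = segment._annulus_contrast(
            gray, np.array([c_true]), r)[0]
        far = np.hypot(centers[:, 0] - c_true[0],
                       centers[:, 1] - c_true[1]) >= 5.0
        assert at_truth > contrast[far].max()


# ----------------------------------------------------------------------------
# CLR spot
# ----------------------------------------------------------------------------

class TestCLR:
    def test_identity_offset(self):
        spec = make_scene(
            left=synthgen.EyeSpec((805.0, 531.0), 56.0, 34.0,
                                  clr_offset=(0.0, 0.0)),
            head_tilt_deg=0.0)
        from photoscreen import localize

        img, _, truth = synthgen.render_exam(spec)
        lm = localize.load_landmarks(truth.landmarks)
        left, _ = localize.extract_eye_patches(img, lm)
        mask = segment.build_roi_mask(left.pixels)
        limb = segment.detect_limbus_hirschberg(
            left.pixels, mask, corner_distance=left.corner_distance)
        clr = segment.detect_clr(left.pixels, limb)
        c_true = left.from_corrected(truth.limbus_center_left)[0]
        assert np.hypot(*(np.asarray(clr.center) - c_true)) <= 0.5

    def test_known_offset_recovered(self, scene_patches):
        truth = scene_patches["truth"]
        m = measure_eye(scene_patches, "left")
        off = np.asarray(m["clr"].center) - np.asarray(m["limbus"].center)
        assert np.hypot(off[0] - truth.offsets.dx_left,
                        off[1] - truth.offsets.dy_left) <= 1.0

    def test_no_reflection_error(self):
        patch = np.zeros((60, 60, 3), dtype=np.uint8)
        patch[:, :, 0] = 30  # dull red, but min-channel stays 0 everywhere
        limb = segment.LimbusCircle((30.0, 30.0), 20.0, 0.0, "hirschberg")
        clr = segment.detect_clr(patch, limb)  # tolerance makes all max
        # a truly empty candidate set needs the disk outside the patch
        with pytest.raises(DetectionError):
            segment.detect_clr(patch, segment.LimbusCircle(
                (-100.0, -100.0), 5.0, 0.0, "hirschberg"))

    def test_larger_cluster_wins_and_tie_break(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[10:13, 5:8] = 255  # 9 px
        img[25:29, 20:25] = 255  # 20 px -> larger wins
        limb = segment.LimbusCircle((20.0, 20.0), 19.0, 0.0, "hirschberg")
        clr = segment.detect_clr(img, limb)
        assert 20 <= clr.center[0] <= 25 and 24 <= clr.center[1] <= 29
        # exact tie: topmost-then-leftmost centroid wins
        img2 = np.zeros((40, 40, 3), dtype=np.uint8)
        img2[10:13, 10:13] = 255
        img2[25:28, 25:28] = 255
        clr2 = segment.detect_clr(img2, limb)
        assert clr2.center[0] <= 13 and clr2.center[1] <= 13

    def test_inscribed_circle_against_brute_force(self):
        """Distance-transform inscribed circle equals the brute-force
        largest contained circle on 100 random small components."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            h, w = rng.integers(8, 41, size=2)
            comp = np.zeros((h + 2, w + 2), dtype=bool)
            # random union of rectangles and disks, away from the border
            for _ in range(rng.integers(1, 4)):
                if rng.random() < 0.5:
                    y0, x0 = rng.integers(1, h), rng.integers(1, w)
                    comp[y0:y0 + rng.integers(2, h), x0:x0 + rng.integers(2, w)] = True
                else:
                    yy, xx = np.mgrid[0:h + 2, 0:w + 2]
                    cy, cx = rng.integers(1, h), rng.integers(1, w)
                    comp[(yy - cy) ** 2 + (xx - cx) ** 2
                         <= int(rng.integers(2, 10)) ** 2] = True
            comp[0, :] = comp[-1, :] = comp[:, 0] = comp[:, -1] = False
            if not comp.any():
                continue
            (cx_i, cy_i), r_i = segment.inscribed_circle(comp)
            # brute force: for every inside pixel, its clearance is the
            # distance to the nearest outside pixel
            ys, xs = np.nonzero(comp)
            oys, oxs = np.nonzero(~comp)
            d2 = (ys[:, None] - oys[None, :]) ** 2 \
                + (xs[:, None] - oxs[None, :]) ** 2
            clearance = np.sqrt(d2.min(axis=1))
            assert r_i == pytest.approx(clearance.max(), abs=1e-9)
            best = np.flatnonzero(np.isclose(clearance, clearance.max()))
            assert any(ys[b] == cy_i and xs[b] == cx_i for b in best)


# ----------------------------------------------------------------------------
# Minimum-area enclosing ellipse and crescent
# ----------------------------------------------------------------------------

def slsqp_min_ellipse_area(points):
    """Independent primal solve: minimize ellipse area s.t. containment."""
    from scipy.optimize import minimize

    pts = np.asarray(points, dtype=float)
    c0 = pts.mean(axis=0)
    r0 = max(np.linalg.norm(pts - c0, axis=1).max(), 1e-3)

    def unpack(v):
        l1, l2, l3, cx, cy = v
        L = np.array([[l1, 0.0], [l2, l3]])
        return L @ L.T, np.array([cx, cy])

    def neg_logdet(v):
        l1, l2, l3 = v[0], v[1], v[2]
        return -2.0 * (np.log(abs(l1) + 1e-12) + np.log(abs(l3) + 1e-12))

    cons = [{
        "type": "ineq",
        "fun": lambda v, p=p: 1.0 - (p - unpack(v)[1]) @ unpack(v)[0]
        @ (p - unpack(v)[1]),
    } for p in pts]
    x0 = np.array([1.0 / r0, 0.0, 1.0 / r0, c0[0], c0[1]])
    res = minimize(neg_logdet, x0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    A, _ = unpack(res.x)
    return np.pi / np.sqrt(np.linalg.det(A))


class TestMinEnclosingEllipse:
    def test_contains_and_matches_independent_solver(self):
        """Khachiyan ellipse matches an SLSQP primal solve of the same
        problem on 100 random point sets of up to 12 points."""
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 13))
            pts = rng.uniform(-10, 10, size=(n, 2))
            if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
                continue
            center, (a, b), angle = segment.min_enclosing_ellipse(pts)
            # containment (within numerical slack); the orientation is
            # counterclockwise-on-screen from +x with y pointing down,
            # so the major-axis direction is (cos t, -sin t)
            t = np.deg2rad(angle)
            u1 = np.array([np.cos(t), -np.sin(t)])
            u2 = np.array([np.sin(t), np.cos(t)])
            q = (pts - center) @ np.column_stack([u1, u2])
            assert np.all((q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 <= 1 + 1e-6)
            area = np.pi * a * b
            ref = slsqp_min_ellipse_area(pts)
            assert area <= ref * (1 + 5e-3) + 1e-9
            checked += 1

    def test_degenerate_inputs(self):
        (cx, cy), axes, _ = segment.min_enclosing_ellipse([[3.0, 4.0]])
        assert (cx, cy) == (3.0, 4.0)
        # collinear points yield a valid thin ellipse containing them
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        center, (a, b), angle = segment.min_enclosing_ellipse(pts)
        assert a >= np.hypot(1.0, 1.0) - 1e-3


class TestCrescent:
    def test_zero_width_empty(self, scene_patches):
        m = measure_eye(scene_patches, "right")  # rendered without crescent
        assert m["crescent"].width_mm == 0.0
        assert m["crescent"].side == screen.NO_CRESCENT
        assert m["crescent"].pixel_count == 0

    def test_width_and_side(self, scene_patches):
        truth = scene_patches["truth"]
        m = measure_eye(scene_patches, "left")
        assert m["crescent"].width_mm == pytest.approx(
            truth.crescent_width_left_mm, abs=0.1)
        assert m["crescent"].side == truth.crescent_side_left

    def test_away_side(self):
        spec = make_scene(
            left=synthgen.EyeSpec((805.0, 531.0), 56.0, 34.0,
                                  crescent_width_mm=1.5,
                                  crescent_side=screen.AWAY_FROM_FLASH),
            head_tilt_deg=0.0, embed_qr=False)
        from photoscreen import localize

        h, r, truth = synthgen.render_exam(spec)
        lm = localize.load_landmarks(truth.landmarks)
        pl, _ = localize.extract_eye_patches(h, lm)
        rl, _ = localize.extract_eye_patches(r, lm)
        mask = segment.build_roi_mask(pl.pixels)
        limb = segment.detect_limbus_hirschberg(
            pl.pixels, mask, corner_distance=pl.corner_distance)
        clr = segment.detect_clr(pl.pixels, limb)
        cres = segment.detect_crescent(rl.pixels, limb, clr, 0.1)
        assert cres.side == screen.AWAY_FROM_FLASH
        assert cres.width_mm == pytest.approx(1.5, abs=0.1)

    def test_full_pupil_flag(self):
        # a pupil nearly as large as the limbus, almost fully covered in
        # red, exceeds 70% of the limbus disk and reports the limbus
        # diameter as width
        spec = make_scene(
            left=synthgen.EyeSpec((805.0, 531.0), 40.0, 37.0,
                                  crescent_width_mm=7.0),
            head_tilt_deg=0.0, embed_qr=False)
        from photoscreen import localize

        h, r, truth = synthgen.render_exam(spec)
        lm = localize.load_landmarks(truth.landmarks)
        pl, _ = localize.extract_eye_patches(h, lm)
        rl, _ = localize.extract_eye_patches(r, lm)
        mask = segment.build_roi_mask(pl.pixels)
        limb = segment.detect_limbus_hirschberg(
            pl.pixels, mask, corner_distance=pl.corner_distance)
        clr = segment.detect_clr(pl.pixels, limb)
        cres = segment.detect_crescent(rl.pixels, limb, clr, 0.1)
        assert cres.full_pupil
        assert cres.width_mm == pytest.approx(0.1 * 2 * limb.radius, rel=0.05)

    def test_monotone_in_rendered_width(self):
        """Measured width is non-decreasing over a 0 -> 3 mm sweep."""
        from photoscreen import localize

        widths = [0.0, 0.4, 0.8, 1.2, 1.8, 2.4, 3.0]
        measured = []
        for w in widths:
            spec = make_scene(
                left=synthgen.EyeSpec((805.0, 531.0), 56.0, 34.0,
                                      crescent_width_mm=w),
                head_tilt_deg=0.0, embed_qr=False)
            h, r, truth = synthgen.render_exam(spec)
            lm = localize.load_landmarks(truth.landmarks)
            pl, _ = localize.extract_eye_patches(h, lm)
            rl, _ = localize.extract_eye_patches(r, lm)
            mask = segment.build_roi_mask(pl.pixels)
            limb = segment.detect_limbus_hirschberg(
                pl.pixels, mask, corner_distance=pl.corner_distance)
            clr = segment.detect_clr(pl.pixels, limb)
            measured.append(segment.detect_crescent(
                rl.pixels, limb, clr, 0.1).width_mm)
        assert all(b >= a - 1e-9 for a, b in zip(measured, measured[1:]))
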