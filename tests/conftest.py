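import dataclasses

import pytest

from photoscreen import localize, screen, segment, synthgen


def make_scene(**overrides) -> synthgen.EyeSceneSpec:
    """A mid-complexity scene: offsets, crescents, tilt, mild occlusion."""
    left = overrides.pop("left", None) or synthgen.EyeSpec(
        (805.0, 531.0), 56.0, 34.0, clr_offset=(12.0, -4.0),
        crescent_width_mm=1.5, lid_occlusion_deg=(15.0, 10.0),
    )
    right = overrides.pop("right", None) or synthgen.EyeSpec(
        (225.0, 529.0), 56.0, 34.0, clr_offset=(2.0, 1.0),
        crescent_width_mm=0.0, lid_occlusion_deg=(15.0, 10.0),
    )
    defaults = dict(left=left, right=right, head_tilt_deg=5.0,
                    pixels_per_mm=10.0)
    defaults.update(overrides)
    return synthgen.EyeSceneSpec(**defaults)


@pytest.fixture(scope="session")
def scene():
    spec = make_scene()
    hirschberg, redreflex, truth = synthgen.render_exam(spec)
    return spec, hirschberg, redreflex, truth


@pytest.fixture(scope="session")
def scene_patches(scene):
    """Tilt-corrected eye patches of the session scene, both frames."""
    spec, hirschberg, redreflex, truth = scene
    lm = localize.load_landmarks(truth.landmarks)
    h_left, h_right = localize.extract_eye_patches(hirschberg, lm)
    r_left, r_right = localize.extract_eye_patches(redreflex, lm)
    return {
        "spec": spec, "truth": truth, "landmarks": lm,
        "h": {"left": h_left, "right": h_right},
        "r": {"left": r_left, "right": r_right},
    }


def measure_eye(patches, eye: str, alpha: float | None = None):
    """Run the full per-eye measurement chain on the fixture patches."""
    spec = patches["spec"]
    alpha = alpha if alpha is not None else 1.0 / spec.pixels_per_mm
    hp, rp = patches["h"][eye], patches["r"][eye]
    mask = segment.build_roi_mask(hp.pixels)
    limbus = segment.detect_limbus_hirschberg(
        hp.pixels, mask, corner_distance=hp.corner_distance)
    clr = segment.detect_clr(hp.pixels, limbus)
    limbus_red = segment.refine_limbus_photorefraction(rp.pixels, limbus)
    crescent = segment.detect_crescent(
        rp.pixels, limbus_red, clr, alpha, flash_side=spec.flash_side)
    return {"mask": mask, "limbus": limbus, "clr": clr,
            "limbus_red": limbus_red, "crescent": crescent}


def random_cohort_scene(rng, noise_sigma=0.0, index=0):
    cohort = synthgen.CohortSpec(noise_sigma=noise_sigma, seed=0)
    spec, _ = synthgen.sample_scene_specs(cohort, index, rng)
    return spec


def write_case(tmp_path, spec, case_id="C0"):
    """Render a spec to disk as a one-attempt exam case."""
    from PIL import Image
    import json

    from photoscreen import pipeline

    h, r, truth = synthgen.render_exam(spec)
    hp = tmp_path / f"{case_id}_h.png"
    rp = tmp_path / f"{case_id}_r.png"
    lp = tmp_path / f"{case_id}_lm.json"
    Image.fromarray(h).save(hp)
    Image.fromarray(r).save(rp)
    lp.write_text(json.dumps(truth.landmarks))
    case = pipeline.ExamCase(
        examinee_id=case_id,
        attempts=(pipeline.ExamAttempt(hp, rp, lp),),
    )
    return case, truth


def closed_eye_variant(spec):
    return dataclasses.replace(
        spec,
        left=dataclasses.replace(spec.left, lid_occlusion_deg=(80.0, 80.0)),
        right=dataclasses.replace(spec.right, lid_occlusion_deg=(80.0, 80.0)),
    )
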