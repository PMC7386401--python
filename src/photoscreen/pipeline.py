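"""Exam orchestration: one-step analysis, batch runs and evaluation.

``run_exam`` wires the stages in the fixed protocol order — landmark
loading and openness gating, tilt correction and patch extraction, limbus
and CLR detection on the Hirschberg still (the higher signal-to-noise
image is processed first), fixed-radius limbus refinement and crescent
extraction on the red-reflex frame, QR scale decoding, and risk
classification.  Cases may list several image-pair attempts (the field
protocol allows a retake after a blink); the first pair passing the
quality gates is used and the attempt index recorded.

``run_batch`` applies it over a manifest with per-case isolation: one
failing case yields one structured failure record, never an aborted batch.
``evaluate`` scores batch predictions against truth labels per condition;
myopia is counted per eye, so its confusion-matrix total is twice the
number of examinees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import localize, screen, segment
from .errors import MetricUndefinedError, PhotoscreenError, ValidationError


@dataclass(frozen=True)
class ExamAttempt:
    hirschberg_path: Path
    redreflex_path: Path
    landmarks_path: Path


@dataclass(frozen=True)
class ExamCase:
    examinee_id: str
    attempts: tuple[ExamAttempt, ...]
    truth_path: Path | None = None

    def __post_init__(self):
        if not self.attempts:
            raise ValidationError("case must have at least one attempt")


def _load_image(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def case_from_row(row: dict, base_dir: Path | str = ".") -> ExamCase:
    """Build a case from a manifest row (';'-separated per-attempt paths)."""
    base = Path(base_dir)
    hs = str(row["hirschberg_path"]).split(";")
    rs = str(row["redreflex_path"]).split(";")
    ls = str(row["landmarks_path"]).split(";")
    if not len(hs) == len(rs) == len(ls):
        raise ValidationError(
            f"case {row.get('id')}: attempt path lists differ in length"
        )
    truth = row.get("truth_path")
    truth_path = base / truth if isinstance(truth, str) and truth else None
    return ExamCase(
        examinee_id=str(row["id"]),
        attempts=tuple(
            ExamAttempt(base / h, base / r, base / l)
            for h, r, l in zip(hs, rs, ls)
        ),
        truth_path=truth_path,
    )


def analyze_images(examinee_id: str, hirschberg: np.ndarray,
                   redreflex: np.ndarray, landmarks: localize.FaceLandmarks,
                   config: screen.ScreeningConfig = screen.ScreeningConfig()
                   ) -> screen.ScreeningResult:
    """Run the full measurement chain on in-memory images.

    This is the core of :func:`run_exam` without file IO or retry handling:
    scale decode, tilt-corrected patch extraction, per-eye limbus/CLR
    detection on the Hirschberg still, limbus refinement and crescent
    extraction on the red-reflex frame, then classification.
    """
    trace: dict = {}

    # scale first: alpha is needed for the crescent widths
    scale = segment.decode_scale(hirschberg)
    trace["scale"] = scale.to_dict()
    alpha = scale.alpha_mm_per_px

    h_left, h_right = localize.extract_eye_patches(
        hirschberg, landmarks, eta=config.eta)
    r_left, r_right = localize.extract_eye_patches(
        redreflex, landmarks, eta=config.eta)

    per_eye = {}
    for name, hp, rp in (("left", h_left, r_left), ("right", h_right, r_right)):
        mask = segment.build_roi_mask(hp.pixels)
        limbus = segment.detect_limbus_hirschberg(
            hp.pixels, mask, corner_distance=hp.corner_distance)
        clr = segment.detect_clr(hp.pixels, limbus)
        limbus_r = segment.refine_limbus_photorefraction(rp.pixels, limbus)
        crescent = segment.detect_crescent(
            rp.pixels, limbus_r, clr, alpha, flash_side=config.flash_side)
        per_eye[name] = {
            "patch": hp, "limbus": limbus, "clr": clr,
            "limbus_red": limbus_r, "crescent": crescent,
        }
        trace[name] = {
            "limbus": limbus.to_dict(), "clr": clr.to_dict(),
            "limbus_red": limbus_r.to_dict(), "crescent": crescent.to_dict(),
        }

    def corrected_center(eye, which="limbus"):
        d = per_eye[eye]
        return d["patch"].to_corrected(d[which].center)[0]

    offsets = screen.EyeOffsets(
        dx_left=per_eye["left"]["clr"].center[0] - per_eye["left"]["limbus"].center[0],
        dy_left=per_eye["left"]["clr"].center[1] - per_eye["left"]["limbus"].center[1],
        dx_right=per_eye["right"]["clr"].center[0] - per_eye["right"]["limbus"].center[0],
        dy_right=per_eye["right"]["clr"].center[1] - per_eye["right"]["limbus"].center[1],
    )
    gaze = screen.binocular_deviation(offsets, alpha, config.d_mm)
    ipd = screen.interpupillary_distance(
        corrected_center("left"), corrected_center("right"), alpha)
    cl = per_eye["left"]["crescent"]
    cr = per_eye["right"]["crescent"]
    flags = screen.classify(gaze, cl, cr, config)

    notes = []
    if cl.side != screen.NO_CRESCENT and cr.side != screen.NO_CRESCENT \
            and cl.side != cr.side:
        notes.append("opposite-side crescents")
    return screen.ScreeningResult(
        examinee_id=examinee_id,
        gaze=gaze,
        crescent_width_left_mm=cl.width_mm,
        crescent_width_right_mm=cr.width_mm,
        crescent_side_left=cl.side,
        crescent_side_right=cr.side,
        ipd_mm=ipd,
        flags=flags,
        quality_notes=notes,
        trace=trace,
    )


def run_exam(case: ExamCase,
             config: screen.ScreeningConfig = screen.ScreeningConfig()
             ) -> screen.ScreeningResult:
    """Analyze one exam case; deterministic for fixed inputs and config.

    Attempts are tried in order; the first pair whose eyes pass the
    openness gate and whose structures are all detected yields the result
    (with the attempt index and, when retried, a quality note).  If every
    attempt fails, the last stage error propagates.
    """
    last_err: PhotoscreenError | None = None
    for idx, attempt in enumerate(case.attempts):
        try:
            landmarks = localize.load_landmarks(attempt.landmarks_path)
            result = analyze_images(
                case.examinee_id,
                _load_image(attempt.hirschberg_path),
                _load_image(attempt.redreflex_path),
                landmarks, config,
            )
        except PhotoscreenError as err:
            last_err = err
            continue
        result.attempt_index = idx
        if idx > 0:
            result.quality_notes.append(f"retried: attempt {idx + 1} used")
        return result
    assert last_err is not None
    raise last_err


@dataclass
class CaseFailure:
    examinee_id: str
    stage: str
    message: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortReport:
    results: list[screen.ScreeningResult] = field(default_factory=list)
    failures: list[CaseFailure] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.results) + len(self.failures)

    @property
    def one_shot_rate(self) -> float:
        """Fraction of successful cases that passed on the first attempt."""
        if not self.results:
            return float("nan")
        return sum(r.attempt_index == 0 for r in self.results) / len(self.results)

    def to_dict(self) -> dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "failures": [f.to_dict() for f in self.failures],
            "one_shot_rate": self.one_shot_rate,
        }


def load_manifest(manifest_path) -> list[ExamCase]:
    import pandas as pd

    path = Path(manifest_path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError("manifest lists no cases")
    return [case_from_row(row, path.parent) for row in df.to_dict("records")]


def run_batch(manifest_path,
              config: screen.ScreeningConfig = screen.ScreeningConfig(),
              out_dir=None) -> CohortReport:
    """Run every case in a manifest with per-case isolation.

    When ``out_dir`` is given, writes ``results.json`` (full report) and
    ``summary.csv`` (one row per successful case).
    """
    cases = load_manifest(manifest_path)
    report = CohortReport()
    for case in cases:
        try:
            report.results.append(run_exam(case, config))
        except PhotoscreenError as err:
            stage = getattr(err, "stage", "") or type(err).__name__
            report.failures.append(
                CaseFailure(case.examinee_id, stage, str(err)))
        except (OSError, ValueError) as err:  # unreadable/corrupt inputs
            report.failures.append(
                CaseFailure(case.examinee_id, "input", str(err)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(
            json.dumps(report.to_dict(), sort_keys=True, indent=1))
        import pandas as pd

        rows = []
        for r in report.results:
            rows.append({
                "id": r.examinee_id,
                "theta_horizontal_deg": r.gaze.horizontal,
                "theta_vertical_deg": r.gaze.vertical,
                "crescent_left_mm": r.crescent_width_left_mm,
                "crescent_right_mm": r.crescent_width_right_mm,
                "ipd_mm": r.ipd_mm,
                "strabismus": r.flags.strabismus,
                "refractive_left": r.flags.refractive_left,
                "refractive_right": r.flags.refractive_right,
                "anisometropia": r.flags.anisometropia,
                "attempt_index": r.attempt_index,
            })
        pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    return report


CONDITIONS = ("strabismus", "myopia", "anisometropia")


def _predicted_myopia(result: screen.ScreeningResult, eye: str) -> bool:
    # a fully lit pupil leaves the direction indeterminate; for screening it
    # still counts toward the myopia tally (severe error of either sign)
    risk = getattr(result.flags, f"refractive_{eye}")
    direction = getattr(result.flags, f"direction_{eye}")
    return bool(risk and direction in (screen.MYOPIC, screen.INDETERMINATE))


def evaluate(report: CohortReport, truths: dict[str, dict]
             ) -> dict[str, tuple[screen.ConfusionMatrix, screen.Metrics]]:
    """Confusion matrix + metrics per condition.

    ``truths`` maps examinee id to a label dict with keys strabismus,
    myopia_left, myopia_right, anisometropia.  Myopia is tallied per eye
    (total count = 2 x examinees); ids missing on either side are an error.
    """
    pred_ids = {r.examinee_id for r in report.results}
    orphans = sorted(pred_ids.symmetric_difference(truths))
    if orphans:
        raise ValidationError(
            f"id mismatch between reports and truths: {orphans}"
        )
    counts = {c: {"tp": 0, "fp": 0, "tn": 0, "fn": 0} for c in CONDITIONS}

    def tally(cond, predicted, actual):
        key = ("tp" if actual else "fp") if predicted else ("fn" if actual else "tn")
        counts[cond][key] += 1

    for r in report.results:
        t = truths[r.examinee_id]
        tally("strabismus", r.flags.strabismus, t["strabismus"])
        tally("myopia", _predicted_myopia(r, "left"), t["myopia_left"])
        tally("myopia", _predicted_myopia(r, "right"), t["myopia_right"])
        tally("anisometropia", r.flags.anisometropia, t["anisometropia"])
    out = {}
    for cond in CONDITIONS:
        cm = screen.ConfusionMatrix(**counts[cond])
        try:
            metrics = screen.confusion_metrics(cm)
        except MetricUndefinedError:
            metrics = None  # an empty stratum leaves that metric undefined
        out[cond] = (cm, metrics)
    return out


def load_truths(manifest_path) -> dict[str, dict]:
    """Read the truth-label dicts referenced by a cohort manifest."""
    truths = {}
    for case in load_manifest(manifest_path):
        if case.truth_path is None:
            raise ValidationError(
                f"case {case.examinee_id} has no truth record")
        data = json.loads(Path(case.truth_path).read_text())
        truths[case.examinee_id] = data["labels"]
    return truths
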