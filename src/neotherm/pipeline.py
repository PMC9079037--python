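"""End-to-end orchestration: phantom generation -> keypoint detection ->
registration -> point transfer -> cpTD extraction -> evaluation.

Mirrors the clinical workflow: keypoints are predicted on the RGB frame
(here by the ground-truth or seeded mock detector), the neck is derived
from the shoulders, the points are transformed into the thermogram through
the subject's registration map (one map per subject — registration is a
per-patient calibration, not per frame), regions are classified central /
peripheral, and the cpTD is extracted from landmark ROI maxima.  Reference
cpTD values use the labeled (ground-truth) IRT keypoints on the same
thermogram.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .keypoints import (
    DEFAULT_REGION_SCHEME,
    DetectorNoiseConfig,
    KeypointSet,
    RegionScheme,
    derive_neck,
    mock_detect,
)
from .phantom import (
    FramePair,
    PhantomConfig,
    PhantomTruth,
    generate_phantom_pair,
    sample_true_map,
)
from .registration import (
    OptimizerSettings,
    PointErrorStats,
    RegistrationMap,
    fit_registration,
    point_transform_error,
    transform_keypoints,
)
from .thermal import (
    DEFAULT_ROI_SIZE,
    BlandAltmanResult,
    CpTDRecord,
    bland_altman,
    compute_cptd,
    cptd_error_stats,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "evaluate_run"]

logger = logging.getLogger("neotherm")

DETECTORS = ("ground_truth", "mock")
REGISTRATION_SOURCES = ("ground_truth", "fit")


@dataclass
class PipelineConfig:
    """One pipeline run over generated phantom subjects.

    ``detector`` is ``"ground_truth"``, ``"mock"`` or any callable taking
    (rgb_frame, truth KeypointSet, rng) and returning a KeypointSet.
    ``registration`` is ``"ground_truth"``, ``"fit"`` or a path to a saved
    map JSON.  The global ``seed`` drives every stochastic component
    (subject maps, frame poses, sensor noise, mock detector, optimizer).
    """

    n_subjects: int = 3
    frames_per_subject: int = 5
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    detector: str | Callable = "ground_truth"
    detector_noise: DetectorNoiseConfig = field(default_factory=DetectorNoiseConfig)
    registration: str = "ground_truth"
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    scheme: RegionScheme = field(default_factory=lambda: DEFAULT_REGION_SCHEME)
    roi_size: int = DEFAULT_ROI_SIZE
    mm_per_px: float = 0.5
    out_dir: str | Path | None = None
    seed: int = 0
    sample_subject_maps: bool = True  # else every subject reuses phantom.true_map

    def __post_init__(self) -> None:
        if isinstance(self.detector, str) and self.detector not in DETECTORS:
            raise ValueError(f"detector must be one of {DETECTORS} or a callable")
        if self.registration not in REGISTRATION_SOURCES and not Path(
                str(self.registration)).suffix == ".json":
            raise ValueError(
                f"registration must be one of {REGISTRATION_SOURCES} or a map JSON path")


@dataclass
class FrameResult:
    subject: int
    frame_id: str
    pair: FramePair
    record: CpTDRecord
    gt_record: CpTDRecord
    det_irt: KeypointSet
    truth: PhantomTruth
    matched_pred: np.ndarray  # (n, 2) transformed detected points
    matched_gt: np.ndarray    # (n, 2) labeled IRT points


@dataclass
class RunReport:
    """Per-frame cpTD rows plus the aggregate agreement statistics.

    Aggregates pool frames across subjects and are recomputable from the
    per-frame data they summarize.
    """

    rows: pd.DataFrame
    frames: list[FrameResult]
    point_error: PointErrorStats | None
    cptd_mae: float | None
    cptd_sd: float | None
    bland: BlandAltmanResult | None
    n_undefined: int
    seed: int
    config_echo: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "results.csv", index=False)


def _make_subject_maps(config: PipelineConfig,
                       rng: np.random.Generator) -> list[RegistrationMap]:
    if config.sample_subject_maps:
        return [sample_true_map(rng, config.phantom.rgb_size)
                for _ in range(config.n_subjects)]
    return [config.phantom.true_map for _ in range(config.n_subjects)]


def _detect(config: PipelineConfig, pair: FramePair, truth: PhantomTruth,
            rng: np.random.Generator) -> KeypointSet:
    if callable(config.detector):
        det = config.detector(pair.rgb, truth.kps_rgb, rng)
    elif config.detector == "ground_truth":
        det = truth.kps_rgb.copy()
    else:  # mock
        w = pair.rgb.shape[1]
        h = pair.rgb.shape[0]
        det = mock_detect(truth.kps_rgb, config.detector_noise,
                          frame_size=(w, h), rng=rng)
    return derive_neck(det)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full extraction over generated phantom subjects.

    For each subject a true map is sampled (or reused from the phantom
    template) and one registration map is obtained — the ground truth, a
    mutual-information fit on the subject's first frame, or a map loaded
    from JSON — and reused for all of that subject's frames.  Per frame the
    detector output is transformed into IRT coordinates and the cpTD
    extracted; the reference cpTD comes from the labeled IRT keypoints.
    Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    t_sections: dict[str, float] = {"generate": 0.0, "register": 0.0,
                                    "detect": 0.0, "extract": 0.0}
    subject_maps = _make_subject_maps(config, rng)
    frames: list[FrameResult] = []
    w_irt, h_irt = config.phantom.irt_size

    for s, true_map in enumerate(subject_maps):
        # generate the subject's frames with mild pose jitter per frame
        pairs, truths = [], []
        t0 = time.perf_counter()
        for f in range(config.frames_per_subject):
            cfg = replace(
                config.phantom,
                true_map=true_map,
                seed=int(rng.integers(2**31)),
                figure_offset_px=tuple(rng.uniform(-25.0, 25.0, 2)
                                       * config.phantom.rgb_size[0] / 1920.0),
                figure_rotation_deg=config.phantom.figure_rotation_deg
                + float(rng.uniform(-5.0, 5.0)),
            )
            pair, truth = generate_phantom_pair(cfg)
            pair.frame_id = f"s{s:02d}_f{f:02d}"
            pair.thermal.frame_id = pair.frame_id
            pairs.append(pair)
            truths.append(truth)
        t_sections["generate"] += time.perf_counter() - t0

        t0 = time.perf_counter()
        if config.registration == "ground_truth":
            reg_map = true_map
        elif config.registration == "fit":
            opt = replace(config.optimizer, seed=int(rng.integers(2**31)))
            reg_map, mi, _ = fit_registration(
                pairs[0].rgb, pairs[0].thermal.temperatures, opt)
            logger.info("subject %d registration MI=%.4f", s, mi)
        else:
            reg_map = RegistrationMap.load(config.registration)
        t_sections["register"] += time.perf_counter() - t0

        for pair, truth in zip(pairs, truths):
            t0 = time.perf_counter()
            det = _detect(config, pair, truth, rng)
            t_sections["detect"] += time.perf_counter() - t0

            t0 = time.perf_counter()
            det_irt, oob = transform_keypoints(det, reg_map, (w_irt, h_irt))
            record = compute_cptd(pair.thermal, det_irt, config.scheme,
                                  config.roi_size)
            gt_record = compute_cptd(pair.thermal, truth.kps_irt,
                                     config.scheme, config.roi_size)
            both = (det_irt.labeled_mask() & truth.kps_irt.labeled_mask()
                    & ~oob)
            matched_pred = det_irt.coords()[both]
            matched_gt = truth.kps_irt.coords()[both]
            t_sections["extract"] += time.perf_counter() - t0
            frames.append(FrameResult(
                subject=s, frame_id=pair.frame_id, pair=pair, record=record,
                gt_record=gt_record, det_irt=det_irt, truth=truth,
                matched_pred=matched_pred, matched_gt=matched_gt,
            ))
            if not record.defined:
                logger.warning("frame %s: cpTD undefined (central n=%d, "
                               "peripheral n=%d)", pair.frame_id,
                               record.n_central, record.n_peripheral)

    rows = pd.DataFrame([
        {
            "subject": fr.subject,
            "frame_id": fr.frame_id,
            "central_mean": fr.record.central_mean,
            "peripheral_mean": fr.record.peripheral_mean,
            "cptd": fr.record.cptd,
            "gt_cptd": fr.gt_record.cptd,
            "n_central": fr.record.n_central,
            "n_peripheral": fr.record.n_peripheral,
            "excluded_keypoints": ";".join(fr.record.excluded),
        }
        for fr in frames
    ])

    est = [fr.record.cptd for fr in frames]
    gt = [fr.gt_record.cptd for fr in frames]
    defined_pairs = [
        (e, g) for e, g in zip(est, gt) if e is not None and g is not None
    ]
    n_undefined = sum(1 for fr in frames if not fr.record.defined)
    cptd_mae = cptd_sd = None
    bland = None
    if defined_pairs:
        cptd_mae, cptd_sd = cptd_error_stats(est, gt)
    if len(defined_pairs) >= 2:
        bland = bland_altman(est, gt)

    all_pred = np.concatenate([fr.matched_pred for fr in frames]) \
        if frames else np.empty((0, 2))
    all_gt = np.concatenate([fr.matched_gt for fr in frames]) \
        if frames else np.empty((0, 2))
    point_error = None
    if len(all_pred) >= 1:
        point_error = point_transform_error(all_pred, all_gt, config.mm_per_px)

    report = RunReport(
        rows=rows,
        frames=frames,
        point_error=point_error,
        cptd_mae=cptd_mae,
        cptd_sd=cptd_sd,
        bland=bland,
        n_undefined=n_undefined,
        seed=config.seed,
        config_echo={
            "n_subjects": config.n_subjects,
            "frames_per_subject": config.frames_per_subject,
            "detector": config.detector if isinstance(config.detector, str)
            else getattr(config.detector, "__name__", "callable"),
            "registration": str(config.registration),
            "roi_size": config.roi_size,
            "mm_per_px": config.mm_per_px,
            "seed": config.seed,
        },
        stage_seconds=t_sections,
    )
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report


def evaluate_run(
    report: RunReport,
    truths: list[PhantomTruth] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-subject and pooled evaluation tables from a run report.

    Produces the point-transfer table (per-subject MAE/SD of |dx|, |dy| in
    px and mm plus a pooled Total row), the cpTD agreement table (per-
    subject MAE/SD plus pooled Total) and the Bland-Altman summary.  The
    Total rows pool all frames rather than averaging subject means.
    """
    if truths is not None and len(truths) != len(report.frames):
        raise ValueError(
            f"{len(truths)} truth entries for {len(report.frames)} frames")
    subjects = sorted({fr.subject for fr in report.frames})

    point_rows = []
    for label, sel in [*((str(s), [fr for fr in report.frames if fr.subject == s])
                         for s in subjects),
                       ("Total", report.frames)]:
        pred = np.concatenate([fr.matched_pred for fr in sel]) if sel else np.empty((0, 2))
        gt = np.concatenate([fr.matched_gt for fr in sel]) if sel else np.empty((0, 2))
        if len(pred) == 0:
            continue
        st = point_transform_error(pred, gt, report.config_echo["mm_per_px"])
        point_rows.append({
            "subject": label, "n_points": st.n,
            "mae_x_px": st.mae_x_px, "sd_x_px": st.sd_x_px,
            "mae_y_px": st.mae_y_px, "sd_y_px": st.sd_y_px,
            "mae_x_mm": st.mae_x_mm, "sd_x_mm": st.sd_x_mm,
            "mae_y_mm": st.mae_y_mm, "sd_y_mm": st.sd_y_mm,
        })
    point_table = pd.DataFrame(point_rows)

    cptd_rows = []
    for label, sel in [*((str(s), [fr for fr in report.frames if fr.subject == s])
                         for s in subjects),
                       ("Total", report.frames)]:
        est = [fr.record.cptd for fr in sel]
        gt = [fr.gt_record.cptd for fr in sel]
        pairs = [(e, g) for e, g in zip(est, gt) if e is not None and g is not None]
        if not pairs:
            cptd_rows.append({"subject": label, "n_frames": 0,
                              "mae_c": np.nan, "sd_c": np.nan})
            continue
        mae, sd = cptd_error_stats(est, gt)
        cptd_rows.append({"subject": label, "n_frames": len(pairs),
                          "mae_c": mae, "sd_c": sd})
    cptd_table = pd.DataFrame(cptd_rows)

    ba_table = pd.DataFrame()
    if report.bland is not None:
        b = report.bland
        ba_table = pd.DataFrame([{
            "mean_difference_c": b.mean_difference,
            "sd_difference_c": b.sd_difference,
            "loa_lower_c": b.loa_lower,
            "loa_upper_c": b.loa_upper,
            "n": len(b.differences),
        }])

    tables = {"point_transform": point_table, "cptd": cptd_table,
              "bland_altman": ba_table}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        point_table.to_csv(out / "point_transform_eval.csv", index=False)
        cptd_table.to_csv(out / "cptd_eval.csv", index=False)
        ba_table.to_csv(out / "bland_altman.csv", index=False)
    return tables
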