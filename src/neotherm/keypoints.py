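"""Body-landmark data model, neck derivation, region classification and
OKS-based detector evaluation.

The landmark vocabulary is the 17-point COCO person convention (nose, eyes,
ears, shoulders, elbows, wrists, hips, knees, ankles) plus a derived ``neck``
placed at the midpoint of the two shoulders, for 18 named slots in a fixed
order.  Visibility follows COCO: 0 = not labeled, 1 = labeled but occluded,
2 = labeled and visible.  The subject scale used by OKS is the square root of
the annotated patient-mask area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "COCO_KEYPOINT_NAMES",
    "KEYPOINT_NAMES",
    "COCO_SIGMAS",
    "OKS_KAPPAS",
    "KeypointSet",
    "RegionScheme",
    "DEFAULT_REGION_SCHEME",
    "DetectorNoiseConfig",
    "derive_neck",
    "classify_regions",
    "mock_detect",
    "oks",
    "evaluate_ap_ar",
    "read_coco_keypoints",
    "write_coco_keypoints",
]

COCO_KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: 18-slot vocabulary: the 17 COCO points with the derived neck appended last.
KEYPOINT_NAMES: tuple[str, ...] = COCO_KEYPOINT_NAMES + ("neck",)

N_KEYPOINTS = len(KEYPOINT_NAMES)

#: Published COCO keypoint annotation sigmas; the neck inherits the shoulder value.
COCO_SIGMAS = np.array(
    [0.026, 0.025, 0.025, 0.035, 0.035, 0.079, 0.079, 0.072, 0.072,
     0.062, 0.062, 0.107, 0.107, 0.087, 0.087, 0.089, 0.089, 0.079]
)

#: Per-keypoint OKS constants k_i. The canonical COCO evaluator uses
#: k_i = 2*sigma_i inside exp(-d^2 / (2 s^2 k_i^2)).
OKS_KAPPAS = 2.0 * COCO_SIGMAS

_NAME_INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}


@dataclass
class KeypointSet:
    """Named 2D body landmarks for one subject in one frame.

    Coordinates are 0-based pixel coordinates (x = column, y = row, origin
    top-left, referring to pixel centers).
    """

    x: np.ndarray
    y: np.ndarray
    visibility: np.ndarray
    confidence: np.ndarray = None  # type: ignore[assignment]
    scale_area: float = 0.0
    neck_derived: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=int)
        if self.confidence is None:
            self.confidence = np.ones(N_KEYPOINTS, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        for arr, label in ((self.x, "x"), (self.y, "y"),
                           (self.visibility, "visibility"),
                           (self.confidence, "confidence")):
            if arr.shape != (N_KEYPOINTS,):
                raise ValueError(
                    f"{label} must have exactly {N_KEYPOINTS} entries, got {arr.shape}"
                )

    @classmethod
    def from_dict(cls, coords: dict[str, tuple[float, float]],
                  scale_area: float = 0.0, visibility: int = 2) -> "KeypointSet":
        """Build a set from a name -> (x, y) mapping; unnamed slots get visibility 0."""
        x = np.zeros(N_KEYPOINTS)
        y = np.zeros(N_KEYPOINTS)
        v = np.zeros(N_KEYPOINTS, dtype=int)
        for name, (px, py) in coords.items():
            i = _NAME_INDEX[name]
            x[i], y[i], v[i] = px, py, visibility
        return cls(x=x, y=y, visibility=v, scale_area=scale_area)

    @property
    def names(self) -> tuple[str, ...]:
        return KEYPOINT_NAMES

    def index(self, name: str) -> int:
        return _NAME_INDEX[name]

    def get(self, name: str) -> tuple[float, float, int]:
        i = _NAME_INDEX[name]
        return float(self.x[i]), float(self.y[i]), int(self.visibility[i])

    def labeled_mask(self) -> np.ndarray:
        """Boolean mask of keypoints with visibility >= 1."""
        return self.visibility >= 1

    def coords(self) -> np.ndarray:
        """(18, 2) array of (x, y)."""
        return np.stack([self.x, self.y], axis=1)

    def copy(self) -> "KeypointSet":
        return KeypointSet(
            x=self.x.copy(), y=self.y.copy(),
            visibility=self.visibility.copy(),
            confidence=self.confidence.copy(),
            scale_area=self.scale_area,
            neck_derived=self.neck_derived,
        )


def derive_neck(kps: KeypointSet) -> KeypointSet:
    """Return a copy with the neck set to the midpoint of the two shoulders.

    The neck is labeled only when both shoulders carry visibility >= 1; its
    visibility is the minimum of the two shoulders'.  Any pre-existing neck
    entry is overwritten.
    """
    out = kps.copy()
    ls, rs = _NAME_INDEX["left_shoulder"], _NAME_INDEX["right_shoulder"]
    neck = _NAME_INDEX["neck"]
    if kps.visibility[ls] >= 1 and kps.visibility[rs] >= 1:
        out.x[neck] = 0.5 * (kps.x[ls] + kps.x[rs])
        out.y[neck] = 0.5 * (kps.y[ls] + kps.y[rs])
        out.visibility[neck] = min(kps.visibility[ls], kps.visibility[rs])
        out.confidence[neck] = min(kps.confidence[ls], kps.confidence[rs])
    else:
        out.x[neck] = 0.0
        out.y[neck] = 0.0
        out.visibility[neck] = 0
    out.neck_derived = True
    return out


@dataclass(frozen=True)
class RegionScheme:
    """Partition of the 18 landmark names into central and peripheral groups."""

    central: tuple[str, ...]
    peripheral: tuple[str, ...]

    def __post_init__(self) -> None:
        names = set(self.central) | set(self.peripheral)
        unknown = names - set(KEYPOINT_NAMES)
        if unknown:
            raise ValueError(f"unknown keypoint names in scheme: {sorted(unknown)}")
        if set(self.central) & set(self.peripheral):
            raise ValueError("central and peripheral groups overlap")
        if names != set(KEYPOINT_NAMES):
            missing = set(KEYPOINT_NAMES) - names
            raise ValueError(f"scheme must cover all keypoints; missing {sorted(missing)}")
        if not self.central or not self.peripheral:
            raise ValueError("scheme needs at least one central and one peripheral name")

    def region_of(self, name: str) -> str:
        return "central" if name in self.central else "peripheral"

    def swapped(self) -> "RegionScheme":
        return RegionScheme(central=self.peripheral, peripheral=self.central)


#: Facial points and the upper-body landmarks form the central group; the
#: remaining keypoints (limbs and hips) are peripheral.
DEFAULT_REGION_SCHEME = RegionScheme(
    central=("nose", "left_eye", "right_eye", "left_ear", "right_ear",
             "neck", "left_shoulder", "right_shoulder"),
    peripheral=("left_elbow", "right_elbow", "left_wrist", "right_wrist",
                "left_hip", "right_hip", "left_knee", "right_knee",
                "left_ankle", "right_ankle"),
)


def classify_regions(
    kps: KeypointSet, scheme: RegionScheme = DEFAULT_REGION_SCHEME
) -> tuple[list[str], list[str]]:
    """Split the labeled keypoints (visibility >= 1) into central and
    peripheral name lists, preserving the canonical slot order."""
    central: list[str] = []
    peripheral: list[str] = []
    for i, name in enumerate(KEYPOINT_NAMES):
        if kps.visibility[i] < 1:
            continue
        (central if name in scheme.central else peripheral).append(name)
    return central, peripheral


@dataclass
class DetectorNoiseConfig:
    """Noise model for the seeded mock detector standing in for a trained
    pose network: isotropic coordinate jitter, random dropout of true
    keypoints and spurious detections."""

    coord_sd: float = 0.0
    dropout_prob: float = 0.0
    false_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.coord_sd < 0:
            raise ValueError("coord_sd must be >= 0")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")


def mock_detect(
    truth: KeypointSet,
    cfg: DetectorNoiseConfig,
    frame_size: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> KeypointSet:
    """Simulate detector output from ground-truth keypoints.

    Each labeled truth keypoint is independently dropped with
    ``dropout_prob``; survivors are jittered by an isotropic Gaussian of
    ``coord_sd`` px and assigned a confidence that decays with the jitter
    magnitude (floor 0.05), so that confidence ordering correlates with
    localization quality.  ``Poisson(false_positive_rate)`` spurious
    detections are placed at uniform-random positions into empty slots with
    confidence drawn uniformly from [0.05, 0.5].  Deterministic for a fixed
    seed.

    Parameters
    ----------
    frame_size : (width, height), optional
        Frame bounds for placing false positives.  When omitted, the truth
        bounding box is used.
    rng : numpy Generator, optional
        Externally-seeded stream; overrides ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    det = truth.copy()
    det.confidence = np.ones(N_KEYPOINTS)
    labeled = truth.labeled_mask()
    # per-keypoint dropout
    drop = rng.random(N_KEYPOINTS) < cfg.dropout_prob
    # jitter (drawn for every slot to keep the stream layout fixed)
    jitter = rng.normal(0.0, 1.0, size=(N_KEYPOINTS, 2)) * cfg.coord_sd
    for i in range(N_KEYPOINTS):
        if not labeled[i]:
            det.visibility[i] = 0
            continue
        if drop[i]:
            det.visibility[i] = 0
            continue
        det.x[i] = truth.x[i] + jitter[i, 0]
        det.y[i] = truth.y[i] + jitter[i, 1]
        if cfg.coord_sd > 0:
            r2 = jitter[i, 0] ** 2 + jitter[i, 1] ** 2
            det.confidence[i] = max(0.05, float(np.exp(-r2 / (2.0 * cfg.coord_sd**2))))
        det.visibility[i] = truth.visibility[i]
    # false positives fill empty slots
    n_fp = int(rng.poisson(cfg.false_positive_rate))
    if frame_size is not None:
        w, h = frame_size
        x_lo, x_hi, y_lo, y_hi = 0.0, float(w - 1), 0.0, float(h - 1)
    else:
        lbl = labeled.nonzero()[0]
        x_lo, x_hi = float(truth.x[lbl].min()), float(truth.x[lbl].max())
        y_lo, y_hi = float(truth.y[lbl].min()), float(truth.y[lbl].max())
    empty = [i for i in range(N_KEYPOINTS) if det.visibility[i] == 0]
    rng.shuffle(empty)
    for i in empty[:n_fp]:
        det.x[i] = rng.uniform(x_lo, x_hi)
        det.y[i] = rng.uniform(y_lo, y_hi)
        det.visibility[i] = 2
        det.confidence[i] = rng.uniform(0.05, 0.5)
    return det


def oks(gt: KeypointSet, det: KeypointSet,
        kappas: np.ndarray = OKS_KAPPAS) -> float:
    """Object keypoint similarity between a ground-truth and a detected set.

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i >= 1] / sum_i [v_i >= 1],
    where d_i is the Euclidean distance between corresponding points,
    s = sqrt(scale_area) the subject scale, and k_i the per-keypoint
    constant.  Labeled ground-truth keypoints the detector missed contribute
    zero to the numerator.
    """
    if gt.scale_area <= 0:
        raise ValueError("gt.scale_area must be > 0 for OKS")
    labeled = gt.labeled_mask()
    n = int(labeled.sum())
    if n == 0:
        raise ValueError("OKS needs at least one labeled ground-truth keypoint")
    s2 = gt.scale_area  # s^2 with s = sqrt(area)
    d2 = (gt.x - det.x) ** 2 + (gt.y - det.y) ** 2
    sim = np.exp(-d2 / (2.0 * s2 * kappas**2))
    sim = np.where(det.visibility >= 1, sim, 0.0)
    return float(sim[labeled].sum() / n)


# ---------------------------------------------------------------------------
# COCO-style AP / AR

OKS_THRESHOLDS = np.arange(0.50, 0.95 + 1e-9, 0.05)
_RECALL_GRID = np.linspace(0.0, 1.0, 101)
MAX_DETECTIONS_PER_FRAME = 20


def _as_frame_lists(sets) -> list[list[KeypointSet]]:
    out = []
    for entry in sets:
        if isinstance(entry, KeypointSet):
            out.append([entry])
        else:
            out.append(list(entry))
    return out


def _match_frame(gts: list[KeypointSet], dets: list[KeypointSet],
                 threshold: float) -> list[tuple[float, bool]]:
    """Greedy per-frame matching in descending detection confidence.

    Returns (score, is_tp) per detection.  Each ground truth is matched at
    most once; a detection is a true positive when its best OKS against a
    still-unmatched ground truth reaches the threshold.
    """
    order = sorted(range(len(dets)),
                   key=lambda i: -_detection_score(dets[i]))
    gt_matched = [False] * len(gts)
    results = []
    for di in order:
        det = dets[di]
        best, best_gi = -1.0, -1
        for gi, gt in enumerate(gts):
            if gt_matched[gi]:
                continue
            score = oks(gt, det)
            if score > best:
                best, best_gi = score, gi
        is_tp = best_gi >= 0 and best >= threshold
        if is_tp:
            gt_matched[best_gi] = True
        results.append((_detection_score(det), is_tp))
    return results


def _detection_score(det: KeypointSet) -> float:
    mask = det.visibility >= 1
    if not mask.any():
        return 0.0
    return float(det.confidence[mask].mean())


def evaluate_ap_ar(gt_sets, det_sets) -> dict[str, float]:
    """COCO keypoint-detection metrics for per-frame GT/detection lists.

    Detections are matched per frame greedily in descending confidence by
    highest OKS.  AP per threshold uses 101-point interpolated
    precision-recall; the reported AP averages thresholds 0.50:0.05:0.95 and
    is scaled to [0, 100].  AP75 is the single-threshold value at 0.75.  AR
    is the mean over thresholds of the recall attained with at most 20
    detections per frame, also x100.
    """
    gt_frames = _as_frame_lists(gt_sets)
    det_frames = _as_frame_lists(det_sets)
    if len(gt_frames) != len(det_frames):
        raise ValueError("gt_sets and det_sets must have the same number of frames")
    n_gt = sum(len(f) for f in gt_frames)
    if n_gt == 0:
        raise ValueError("no ground-truth annotations in any frame")
    # cap detections per frame by confidence
    det_frames = [
        sorted(f, key=_detection_score, reverse=True)[:MAX_DETECTIONS_PER_FRAME]
        for f in det_frames
    ]
    ap_per_t = []
    recall_per_t = []
    for t in OKS_THRESHOLDS:
        scored: list[tuple[float, bool]] = []
        for gts, dets in zip(gt_frames, det_frames):
            scored.extend(_match_frame(gts, dets, t))
        scored.sort(key=lambda sb: -sb[0])
        tp = np.cumsum([1 if b else 0 for _, b in scored])
        fp = np.cumsum([0 if b else 1 for _, b in scored])
        if len(scored) == 0:
            ap_per_t.append(0.0)
            recall_per_t.append(0.0)
            continue
        recall = tp / n_gt
        precision = tp / np.maximum(tp + fp, 1)
        # monotone (from the right) interpolated precision
        for i in range(len(precision) - 2, -1, -1):
            precision[i] = max(precision[i], precision[i + 1])
        prec_at = np.zeros_like(_RECALL_GRID)
        idx = np.searchsorted(recall, _RECALL_GRID, side="left")
        valid = idx < len(precision)
        prec_at[valid] = precision[idx[valid]]
        ap_per_t.append(float(prec_at.mean()))
        recall_per_t.append(float(recall[-1]))
    ap_per_t = np.asarray(ap_per_t)
    return {
        "AP": float(ap_per_t.mean() * 100.0),
        "AP75": float(ap_per_t[np.isclose(OKS_THRESHOLDS, 0.75)][0] * 100.0),
        "AR": float(np.mean(recall_per_t) * 100.0),
    }


# ---------------------------------------------------------------------------
# COCO keypoint JSON I/O

PERSON_CATEGORY_ID = 1


def write_coco_keypoints(
    sets: Sequence[KeypointSet],
    path: str | Path,
    image_names: Sequence[str] | None = None,
    image_sizes: Sequence[tuple[int, int]] | None = None,
    extra: dict | None = None,
) -> None:
    """Write per-frame 18-keypoint sets as a COCO keypoint JSON file.

    One image and one person annotation per set; the annotation's ``area``
    field carries the subject-mask area used as the OKS scale.  ``extra``
    entries are merged into the top-level object (readers ignore unknown
    keys).
    """
    images = []
    annotations = []
    for i, kps in enumerate(sets):
        name = image_names[i] if image_names else f"frame_{i:04d}.png"
        entry: dict = {"id": i + 1, "file_name": name}
        if image_sizes:
            entry["width"], entry["height"] = image_sizes[i]
        images.append(entry)
        triplets: list[float] = []
        for j in range(N_KEYPOINTS):
            triplets.extend([float(kps.x[j]), float(kps.y[j]), int(kps.visibility[j])])
        annotations.append({
            "id": i + 1,
            "image_id": i + 1,
            "category_id": PERSON_CATEGORY_ID,
            "keypoints": triplets,
            "num_keypoints": int(kps.labeled_mask().sum()),
            "area": float(kps.scale_area),
            "iscrowd": 0,
        })
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{
            "id": PERSON_CATEGORY_ID,
            "name": "person",
            "supercategory": "person",
            "keypoints": list(KEYPOINT_NAMES),
            "skeleton": [],
        }],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_keypoints(path: str | Path) -> list[KeypointSet]:
    """Read a COCO keypoint JSON file into per-frame keypoint sets.

    Accepts the 18-point dialect (neck appended last) losslessly; a
    standard 17-point file is accepted with the neck derived from the
    shoulders on load, and the returned sets carry ``neck_derived=True``.
    Frames are ordered by image id.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed COCO JSON in {path}: {exc}") from exc
    categories = {c["id"]: c for c in doc.get("categories", [])}
    if PERSON_CATEGORY_ID not in categories:
        raise ValueError(f"{path}: no person category (id {PERSON_CATEGORY_ID})")
    n_names = len(categories[PERSON_CATEGORY_ID].get("keypoints", []))
    if n_names not in (17, 18):
        raise ValueError(
            f"{path}: expected 17 or 18 keypoints in the person category, got {n_names}"
        )
    by_image: dict[int, dict] = {}
    for ann in doc["annotations"]:
        if ann.get("category_id") != PERSON_CATEGORY_ID:
            raise ValueError(f"{path}: unknown category id {ann.get('category_id')}")
        by_image[ann["image_id"]] = ann
    sets = []
    for image in sorted(doc["images"], key=lambda im: im["id"]):
        ann = by_image.get(image["id"])
        if ann is None:
            continue
        triplets = np.asarray(ann["keypoints"], dtype=float).reshape(-1, 3)
        n_pts = triplets.shape[0]
        if n_pts not in (17, 18):
            raise ValueError(f"{path}: annotation with {n_pts} keypoints")
        x = np.zeros(N_KEYPOINTS)
        y = np.zeros(N_KEYPOINTS)
        v = np.zeros(N_KEYPOINTS, dtype=int)
        x[:n_pts], y[:n_pts], v[:n_pts] = triplets[:, 0], triplets[:, 1], triplets[:, 2]
        kps = KeypointSet(x=x, y=y, visibility=v, scale_area=float(ann.get("area", 0.0)))
        if n_pts == 17:
            kps = derive_neck(kps)  # sets neck_derived
        sets.append(kps)
    return sets
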