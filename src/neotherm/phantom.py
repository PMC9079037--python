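"""Synthetic multimodal phantom: paired RGB / thermography frames of a
neonate-like figure with fully known ground truth.

The clinical recordings this package targets (neonates supine in an open
incubator, imaged by co-mounted RGB and IRT cameras in a dark room) are not
publicly available, so every downstream stage is exercised on a generated
stand-in.  The phantom is a capsule-and-ellipse figure in a fixed supine
pose: an ellipse for the trunk, a disc for the head, and thick line segments
(capsules) along the limb chains shoulder-elbow-wrist and hip-knee-ankle.
The RGB frame shows the figure in skin tones on a dark background
(emulating OLED-only illumination); the thermogram shows the same scene
rendered in the IRT coordinate frame through the inverse of a known
crop+affine map, with skin temperature warm centrally and cooling toward
the limb ends, so the central-peripheral temperature difference is known in
closed form.

Temperature along a limb chain decreases piecewise-linearly with arc
length, with a flat plateau around each joint sized larger than the
extraction window, so the windowed ROI maximum at every landmark equals
that landmark's analytic peak temperature exactly in the noiseless case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .keypoints import (
    DEFAULT_REGION_SCHEME,
    KEYPOINT_NAMES,
    KeypointSet,
    RegionScheme,
    write_coco_keypoints,
)
from .registration import RegistrationMap
from .thermal import ThermalFrame, write_thermal_tiff

__all__ = [
    "CANONICAL_POSE",
    "PhantomConfig",
    "PhantomTruth",
    "FramePair",
    "generate_phantom_pair",
    "write_phantom_dataset",
    "read_phantom_dataset",
    "sample_true_map",
    "analytic_keypoint_temperatures",
]

#: Canonical supine pose (head up, limbs splayed) in a unitless body frame:
#: x right, y down, origin mid-body, total height ~1.  Subject-left is +x.
CANONICAL_POSE: dict[str, tuple[float, float]] = {
    "nose": (0.000, -0.380),
    "left_eye": (0.035, -0.415),
    "right_eye": (-0.035, -0.415),
    "left_ear": (0.070, -0.395),
    "right_ear": (-0.070, -0.395),
    "left_shoulder": (0.140, -0.260),
    "right_shoulder": (-0.140, -0.260),
    "left_elbow": (0.300, -0.120),
    "right_elbow": (-0.300, -0.120),
    "left_wrist": (0.420, 0.040),
    "right_wrist": (-0.420, 0.040),
    "left_hip": (0.090, 0.100),
    "right_hip": (-0.090, 0.100),
    "left_knee": (0.240, 0.280),
    "right_knee": (-0.240, 0.280),
    "left_ankle": (0.360, 0.460),
    "right_ankle": (-0.360, 0.460),
    "neck": (0.000, -0.260),
}

_HEAD_CENTER = (0.0, -0.400)
_LIMB_CHAINS = (
    ("left_shoulder", "left_elbow", "left_wrist"),
    ("right_shoulder", "right_elbow", "right_wrist"),
    ("left_hip", "left_knee", "left_ankle"),
    ("right_hip", "right_knee", "right_ankle"),
)

_SKIN_RGB = np.array([212.0, 172.0, 148.0])      # luminance ~ 180/255
_BACKGROUND_RGB = np.array([10.0, 10.0, 10.0])   # dark environment
_CLOTHING_RGB = np.array([70.0, 78.0, 120.0])


def _default_true_map() -> RegistrationMap:
    return RegistrationMap.from_params(
        tx=40.0, ty=25.0, sx=0.58, sy=0.60, theta_deg=3.0,
        crop_x=150.0, crop_y=100.0,
    )


@dataclass
class PhantomConfig:
    """Study conditions for one generated frame pair.

    Frame sizes default to the clinical sensors (RGB 1920x1200, IRT
    1024x768).  Temperatures default to a physiological neonate under a
    radiant warmer: trunk/head peak 36.8 deg C, limb ends 33.5 deg C,
    background 28.0 deg C; thermogram noise defaults to 0.05 deg C
    (a little above the 20 mK sensor sensitivity).  ``occlusions`` are
    axis-aligned full-RGB-frame rectangles that overwrite the surface
    temperature (clothing) and recolor the RGB — the mechanism behind the
    clinically observed negative cpTD when central or peripheral sites are
    covered.
    """

    rgb_size: tuple[int, int] = (1920, 1200)
    irt_size: tuple[int, int] = (1024, 768)
    true_map: RegistrationMap = field(default_factory=_default_true_map)
    skeleton_pose: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CANONICAL_POSE))
    figure_scale_px: float = 1000.0
    figure_rotation_deg: float = 0.0
    figure_offset_px: tuple[float, float] = (0.0, 0.0)
    t_central: float = 36.8
    t_peripheral: float = 33.5
    t_background: float = 28.0
    noise_sd_irt: float = 0.05
    noise_sd_rgb: float = 4.0
    occlusions: list[tuple[tuple[float, float, float, float], float]] = field(
        default_factory=list)
    seed: int = 0
    # rendering geometry, as fractions of figure_scale_px
    limb_radius_frac: float = 0.035
    head_radius_frac: float = 0.085
    trunk_half_width_frac: float = 0.165
    trunk_half_height_frac: float = 0.205
    #: flat-temperature radius around each joint, full-RGB px; must exceed
    #: the ROI window's half-diagonal mapped back to RGB coordinates for the
    #: landmark ROI maxima to be exact.
    plateau_px: float = 18.0
    mm_per_px: float = 0.5

    def __post_init__(self) -> None:
        for label, (w, h) in (("rgb_size", self.rgb_size), ("irt_size", self.irt_size)):
            if w <= 0 or h <= 0:
                raise ValueError(f"{label} must be strictly positive")
        self.true_map.validate_for_frame(self.rgb_size)
        physiological = self.t_central > self.t_peripheral > self.t_background
        if not physiological and not self.occlusions:
            raise ValueError(
                "need t_central > t_peripheral > t_background for a "
                "physiological phantom (non-physiological orderings are only "
                "meaningful with occlusions simulating clothing)"
            )


@dataclass
class FramePair:
    """One synchronized RGB image + thermogram."""

    rgb: np.ndarray
    thermal: ThermalFrame
    frame_id: str = ""
    mm_per_px: float = 0.5


@dataclass
class PhantomTruth:
    """Ground truth for one generated pair: the map, both keypoint sets,
    per-landmark analytic peak temperatures, and the subject-mask area."""

    true_map: RegistrationMap
    kps_rgb: KeypointSet
    kps_irt: KeypointSet
    kp_peak_temp: dict[str, float]
    mask_area_rgb: float

    def analytic_cptd(self, scheme: RegionScheme = DEFAULT_REGION_SCHEME) -> float:
        """Closed-form cpTD: mean central minus mean peripheral landmark
        peak temperature, in canonical slot order (matching the extraction
        stage's averaging order)."""
        central = [self.kp_peak_temp[n] for n in KEYPOINT_NAMES if n in scheme.central]
        peripheral = [self.kp_peak_temp[n] for n in KEYPOINT_NAMES if n in scheme.peripheral]
        return float(np.mean(central)) - float(np.mean(peripheral))


# ---------------------------------------------------------------------------
# Analytic temperature model


def _pose_rgb(config: PhantomConfig) -> dict[str, np.ndarray]:
    """Place the canonical pose into full-RGB pixel coordinates.

    The figure origin is positioned so that its image under the true map
    lands at the IRT frame center, then shifted by ``figure_offset_px``.
    """
    th = np.radians(config.figure_rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    w_irt, h_irt = config.irt_size
    center = config.true_map.apply_inverse(
        np.array([[(w_irt - 1) / 2.0, (h_irt - 1) / 2.0]]))[0]
    center = center + np.asarray(config.figure_offset_px, dtype=float)
    out = {}
    for name, xy in config.skeleton_pose.items():
        out[name] = center + config.figure_scale_px * (rot @ np.asarray(xy))
    out["__head__"] = center + config.figure_scale_px * (rot @ np.asarray(_HEAD_CENTER))
    return out


def analytic_keypoint_temperatures(config: PhantomConfig) -> dict[str, float]:
    """Closed-form peak temperature at every landmark.

    Head, face, neck, shoulders and hips sit on t_central surfaces; along
    each limb chain the temperature falls linearly with arc length from
    t_central at the proximal joint to t_peripheral at the distal end, so
    mid-chain joints (elbows, knees) get the arc-length-fractional value.
    """
    pose = _pose_rgb(config)
    temps = {name: config.t_central for name in KEYPOINT_NAMES}
    for chain in _LIMB_CHAINS:
        p0, p1, p2 = (pose[n] for n in chain)
        l01 = float(np.linalg.norm(p1 - p0))
        l12 = float(np.linalg.norm(p2 - p1))
        frac = l01 / (l01 + l12) if (l01 + l12) > 0 else 0.5
        temps[chain[1]] = config.t_central + frac * (config.t_peripheral - config.t_central)
        temps[chain[2]] = config.t_peripheral
    return temps


def _chain_profile(arc: np.ndarray, joints_arc: np.ndarray,
                   joints_temp: np.ndarray, plateau: float) -> np.ndarray:
    """Temperature at arc positions along a limb chain: flat within
    ``plateau`` of each joint, linear in between."""
    t = np.empty_like(arc)
    t[:] = joints_temp[-1]
    for k in range(len(joints_arc) - 1):
        a0, a1 = joints_arc[k], joints_arc[k + 1]
        t0, t1 = joints_temp[k], joints_temp[k + 1]
        seg = (arc >= a0) & (arc <= a1)
        lo, hi = a0 + plateau, a1 - plateau
        if hi <= lo:  # plateaus meet: step at the midpoint
            mid = 0.5 * (a0 + a1)
            t[seg] = np.where(arc[seg] <= mid, t0, t1)
            continue
        local = np.clip((arc[seg] - lo) / (hi - lo), 0.0, 1.0)
        t[seg] = t0 + local * (t1 - t0)
    t[arc <= joints_arc[0]] = joints_temp[0]
    t[arc >= joints_arc[-1]] = joints_temp[-1]
    return t


class _Scene:
    """Analytic phantom scene evaluated at arbitrary full-RGB coordinates."""

    def __init__(self, config: PhantomConfig):
        self.config = config
        self.pose = _pose_rgb(config)
        self.kp_temps = analytic_keypoint_temperatures(config)
        s = config.figure_scale_px
        self.limb_radius = config.limb_radius_frac * s
        self.head_radius = config.head_radius_frac * s
        self.trunk_axes = (config.trunk_half_width_frac * s,
                           config.trunk_half_height_frac * s)
        neck = self.pose["neck"]
        hip_mid = 0.5 * (self.pose["left_hip"] + self.pose["right_hip"])
        self.trunk_center = 0.5 * (neck + hip_mid)
        self.trunk_angle = np.radians(config.figure_rotation_deg)

    def _trunk_mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = x - self.trunk_center[0]
        dy = y - self.trunk_center[1]
        c, s = np.cos(self.trunk_angle), np.sin(self.trunk_angle)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        ax, ay = self.trunk_axes
        return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0

    def _head_mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        hc = self.pose["__head__"]
        return (x - hc[0]) ** 2 + (y - hc[1]) ** 2 <= self.head_radius**2

    def _chain_temp(self, x: np.ndarray, y: np.ndarray,
                    chain: tuple[str, str, str]) -> tuple[np.ndarray, np.ndarray]:
        """(mask, temperature) contribution of one limb chain's capsules."""
        pts = [self.pose[n] for n in chain]
        temps = np.array([self.kp_temps[n] for n in chain])
        seg_len = [float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(2)]
        joints_arc = np.array([0.0, seg_len[0], seg_len[0] + seg_len[1]])
        mask = np.zeros(x.shape, dtype=bool)
        temp = np.full(x.shape, -np.inf)
        for i in range(2):
            p, q = pts[i], pts[i + 1]
            d = q - p
            L2 = float(d @ d)
            tproj = ((x - p[0]) * d[0] + (y - p[1]) * d[1]) / L2
            tclip = np.clip(tproj, 0.0, 1.0)
            cx = p[0] + tclip * d[0]
            cy = p[1] + tclip * d[1]
            dist2 = (x - cx) ** 2 + (y - cy) ** 2
            inside = dist2 <= self.limb_radius**2
            arc = joints_arc[i] + tclip * np.sqrt(L2)
            seg_temp = _chain_profile(arc, joints_arc, temps,
                                      self.config.plateau_px)
            temp = np.where(inside, np.maximum(temp, seg_temp), temp)
            mask |= inside
        return mask, temp

    def figure_mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        mask = self._trunk_mask(x, y) | self._head_mask(x, y)
        for chain in _LIMB_CHAINS:
            m, _ = self._chain_temp(x, y, chain)
            mask |= m
        return mask

    def temperature(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Noiseless surface temperature at full-RGB coordinates; occluded
        (clothed) regions take the clothing surface temperature."""
        cfg = self.config
        temp = np.full(x.shape, cfg.t_background)
        core = self._trunk_mask(x, y) | self._head_mask(x, y)
        temp[core] = cfg.t_central
        for chain in _LIMB_CHAINS:
            m, t = self._chain_temp(x, y, chain)
            temp = np.where(m, np.maximum(temp, t), temp)
        for (x0, y0, w, h), t_occ in cfg.occlusions:
            inside = (x >= x0) & (x < x0 + w) & (y >= y0) & (y < y0 + h)
            temp[inside] = t_occ
        return temp

    def rgb(self, width: int, height: int) -> np.ndarray:
        """Noiseless 8-bit RGB rendering on the full RGB grid."""
        xx, yy = np.meshgrid(np.arange(width, dtype=float),
                             np.arange(height, dtype=float))
        img = np.empty((height, width, 3))
        img[:] = _BACKGROUND_RGB
        core = self._trunk_mask(xx, yy) | self._head_mask(xx, yy)
        img[core] = _SKIN_RGB
        shade = {0: 0.92, 1: 0.92, 2: 0.96, 3: 0.96}  # arms darker than legs
        for i, chain in enumerate(_LIMB_CHAINS):
            m, _ = self._chain_temp(xx, yy, chain)
            img[m & ~core] = _SKIN_RGB * shade[i]
        for (x0, y0, w, h), _ in self.config.occlusions:
            inside = (xx >= x0) & (xx < x0 + w) & (yy >= y0) & (yy < y0 + h)
            img[inside] = _CLOTHING_RGB
        return img


def generate_phantom_pair(config: PhantomConfig) -> tuple[FramePair, PhantomTruth]:
    """Generate one synchronized RGB/thermogram pair with ground truth.

    The RGB frame is rendered on its own grid; the thermogram is the same
    analytic scene sampled at IRT pixel locations through the inverse of
    ``config.true_map`` (so the thermogram is exactly the crop+affine image
    of the RGB-frame geometry).  Gaussian sensor noise is added per config;
    identical config + seed reproduces byte-identical outputs.
    """
    config.true_map.validate_for_frame(config.rgb_size)  # also re-checks crop
    scene = _Scene(config)
    w_rgb, h_rgb = config.rgb_size
    w_irt, h_irt = config.irt_size
    rng = np.random.default_rng(config.seed)

    rgb = scene.rgb(w_rgb, h_rgb)
    if config.noise_sd_rgb > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sd_rgb, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    uu, vv = np.meshgrid(np.arange(w_irt, dtype=float),
                         np.arange(h_irt, dtype=float))
    src = config.true_map.apply_inverse(
        np.stack([uu.ravel(), vv.ravel()], axis=1))
    temp = scene.temperature(src[:, 0].reshape(h_irt, w_irt),
                             src[:, 1].reshape(h_irt, w_irt))
    if config.noise_sd_irt > 0:
        temp = temp + rng.normal(0.0, config.noise_sd_irt, size=temp.shape)

    pair = FramePair(
        rgb=rgb,
        thermal=ThermalFrame(temp, mm_per_px=config.mm_per_px,
                             frame_id=f"phantom_{config.seed:05d}"),
        frame_id=f"phantom_{config.seed:05d}",
        mm_per_px=config.mm_per_px,
    )

    # ground truth: keypoints in both frames and the mask area
    coords_rgb = {n: tuple(scene.pose[n]) for n in KEYPOINT_NAMES}
    xx, yy = np.meshgrid(np.arange(w_rgb, dtype=float),
                         np.arange(h_rgb, dtype=float))
    mask_area = float(scene.figure_mask(xx, yy).sum())
    kps_rgb = KeypointSet.from_dict(coords_rgb, scale_area=mask_area)
    irt_xy = config.true_map.apply(kps_rgb.coords())
    kps_irt = kps_rgb.copy()
    kps_irt.x, kps_irt.y = irt_xy[:, 0].copy(), irt_xy[:, 1].copy()
    kps_irt.scale_area = mask_area * abs(config.true_map.det)
    truth = PhantomTruth(
        true_map=config.true_map,
        kps_rgb=kps_rgb,
        kps_irt=kps_irt,
        kp_peak_temp=dict(scene.kp_temps),
        mask_area_rgb=mask_area,
    )
    return pair, truth


def sample_true_map(
    rng: np.random.Generator,
    rgb_size: tuple[int, int] = (1920, 1200),
) -> RegistrationMap:
    """Draw a plausible ground-truth map from the interior of the default
    optimizer bounds (scales around the sensor-size ratio, mild rotation,
    moderate translation and crop), scaled with the RGB frame width."""
    f = rgb_size[0] / 1920.0
    return RegistrationMap.from_params(
        tx=rng.uniform(-80.0, 80.0) * f,
        ty=rng.uniform(-80.0, 80.0) * f,
        sx=rng.uniform(0.45, 0.75),
        sy=rng.uniform(0.45, 0.75),
        theta_deg=rng.uniform(-8.0, 8.0),
        crop_x=rng.uniform(60.0, 300.0) * f,
        crop_y=rng.uniform(40.0, 240.0) * f,
    )


# ---------------------------------------------------------------------------
# Dataset I/O


def write_phantom_dataset(
    pairs: list[FramePair],
    truths: list[PhantomTruth],
    out_dir: str | Path,
):
    """Write a phantom dataset to disk and return the manifest.

    Per pair: the RGB frame as 8-bit PNG and the thermogram as 16-bit
    centikelvin TIFF.  One COCO keypoint JSON holds the RGB and IRT
    annotations (18 keypoints, mask area in the ``area`` field) plus a
    ``phantom_truth`` extension block with the true maps and analytic
    landmark temperatures.  The manifest CSV lists the pairings.
    """
    import pandas as pd
    from PIL import Image

    if not pairs:
        raise ValueError("no frame pairs to write")
    if len(pairs) != len(truths):
        raise ValueError(
            f"{len(pairs)} pairs but {len(truths)} truths; lists must match")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    sets, names, sizes = [], [], []
    for i, (pair, truth) in enumerate(zip(pairs, truths)):
        rgb_name = f"rgb_{i:04d}.png"
        irt_name = f"irt_{i:04d}.tiff"
        Image.fromarray(pair.rgb).save(out / rgb_name)
        write_thermal_tiff(pair.thermal, out / irt_name)
        sets.append(truth.kps_rgb)
        names.append(rgb_name)
        h, w = pair.rgb.shape[:2]
        sizes.append((w, h))
        rows.append({"frame_id": pair.frame_id or f"{i:04d}",
                     "rgb_path": rgb_name, "irt_path": irt_name})
    for i, (pair, truth) in enumerate(zip(pairs, truths)):
        sets.append(truth.kps_irt)
        names.append(rows[i]["irt_path"])
        sizes.append(pair.thermal.size)
    extra = {
        "phantom_truth": [
            {
                "frame_id": rows[i]["frame_id"],
                "true_map": truths[i].true_map.to_dict(),
                "kp_peak_temp": truths[i].kp_peak_temp,
                "mask_area_rgb": truths[i].mask_area_rgb,
            }
            for i in range(len(pairs))
        ]
    }
    write_coco_keypoints(sets, out / "annotations.json", image_names=names,
                         image_sizes=sizes, extra=extra)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_phantom_dataset(out_dir: str | Path):
    """Read back a written phantom dataset.

    Returns (pairs, truths) with keypoint ground truth and true maps
    restored from the annotation JSON; thermograms pass through the 16-bit
    encoding, so temperatures agree with the originals to 0.005 deg C.
    """
    import pandas as pd
    from PIL import Image

    from .keypoints import read_coco_keypoints
    from .thermal import read_thermal_tiff

    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv")
    all_sets = read_coco_keypoints(out / "annotations.json")
    doc = json.loads((out / "annotations.json").read_text())
    truth_blocks = doc.get("phantom_truth", [])
    n = len(manifest)
    pairs, truths = [], []
    for i, row in manifest.iterrows():
        rgb = np.asarray(Image.open(out / row["rgb_path"]))
        thermal = read_thermal_tiff(out / row["irt_path"])
        thermal.frame_id = str(row["frame_id"])
        pairs.append(FramePair(rgb=rgb, thermal=thermal,
                               frame_id=str(row["frame_id"])))
        block = truth_blocks[i]
        truths.append(PhantomTruth(
            true_map=RegistrationMap.from_dict(block["true_map"]),
            kps_rgb=all_sets[i],
            kps_irt=all_sets[n + i],
            kp_peak_temp={k: float(v) for k, v in block["kp_peak_temp"].items()},
            mask_area_rgb=float(block["mask_area_rgb"]),
        ))
    return pairs, truths
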