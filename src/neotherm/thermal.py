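"""Thermogram handling: temperature encoding, keypoint-centered ROI
extraction, the central-peripheral temperature difference (cpTD), and
agreement statistics.

A thermogram is a height x width map of surface temperatures in deg C.  The
16-bit raster encoding is a linear centikelvin mapping,
``raw = round((T + 273.15) * 100)``, which covers [-273.15, 382.2] deg C in
0.01 deg C steps — comfortably finer than the 20 mK sensitivity of clinical
IRT sensors.

The cpTD is the clinical marker: the mean of per-landmark ROI maximum
temperatures over the central body region minus the same mean over the
peripheral region.  Each landmark reading is the maximum temperature inside
a small window (default 10x10 px) centered on the landmark, which makes the
reading robust to registration offsets smaller than the window half-size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .keypoints import DEFAULT_REGION_SCHEME, KEYPOINT_NAMES, KeypointSet, RegionScheme

__all__ = [
    "ThermalFrame",
    "RoiReading",
    "CpTDRecord",
    "encode_temperature",
    "decode_temperature",
    "read_thermal_tiff",
    "write_thermal_tiff",
    "roi_max_temperature",
    "compute_cptd",
    "cptd_error_stats",
    "bland_altman",
    "BlandAltmanResult",
    "DEFAULT_ROI_SIZE",
]

DEFAULT_ROI_SIZE = 10
_KELVIN_OFFSET = 273.15
_RAW_MAX = np.iinfo(np.uint16).max  # 65535 -> 382.2 deg C


def encode_temperature(temperature_c) -> np.ndarray:
    """Encode deg C as 16-bit centikelvin raw counts."""
    t = np.asarray(temperature_c, dtype=float)
    raw = np.rint((t + _KELVIN_OFFSET) * 100.0)
    if np.any(raw < 0) or np.any(raw > _RAW_MAX):
        raise ValueError(
            f"temperature outside encodable range "
            f"[{-_KELVIN_OFFSET}, {_RAW_MAX / 100.0 - _KELVIN_OFFSET}] deg C"
        )
    return raw.astype(np.uint16)


def decode_temperature(raw) -> np.ndarray:
    """Decode 16-bit centikelvin raw counts to deg C."""
    return np.asarray(raw, dtype=float) / 100.0 - _KELVIN_OFFSET


@dataclass
class ThermalFrame:
    """One thermogram: a float temperature map in deg C plus spatial resolution."""

    temperatures: np.ndarray
    mm_per_px: float = 0.5
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 2:
            raise ValueError("temperatures must be a 2-D map")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValueError("temperatures must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in px."""
        h, w = self.temperatures.shape
        return w, h

    def to_raw(self) -> np.ndarray:
        return encode_temperature(self.temperatures)

    @classmethod
    def from_raw(cls, raw: np.ndarray, mm_per_px: float = 0.5,
                 frame_id: str = "") -> "ThermalFrame":
        return cls(decode_temperature(raw), mm_per_px=mm_per_px, frame_id=frame_id)


def write_thermal_tiff(frame: ThermalFrame, path: str | Path) -> None:
    """Write a thermogram as a single-channel 16-bit TIFF in centikelvin,
    with the encoding documented in the image description tag."""
    import tifffile

    tifffile.imwrite(
        str(path),
        frame.to_raw(),
        description="temperature_c = raw / 100 - 273.15",
    )


def read_thermal_tiff(path: str | Path, mm_per_px: float = 0.5) -> ThermalFrame:
    import tifffile

    raw = tifffile.imread(str(path))
    return ThermalFrame.from_raw(raw, mm_per_px=mm_per_px, frame_id=Path(path).stem)


# ---------------------------------------------------------------------------
# ROI extraction


class RoiOutOfBoundsError(ValueError):
    """The ROI center lies outside the thermogram."""


def _roi_bounds(center: float, size: int, limit: int) -> tuple[int, int]:
    # half-open window [round(c) - size//2, round(c) - size//2 + size), clipped
    lo = int(np.rint(center)) - size // 2
    hi = lo + size
    return max(lo, 0), min(hi, limit)


def roi_max_temperature(
    frame: ThermalFrame, center_px: tuple[float, float], roi_size: int = DEFAULT_ROI_SIZE
) -> tuple[float, int]:
    """Maximum temperature in a square window centered on a landmark.

    The window spans columns ``[round(cx) - roi_size//2, ... + roi_size)``
    and rows likewise (half-open, rounded center, floor division for odd
    sizes), clipped to the frame; returns the maximum over the remaining
    pixels and their count.
    """
    if roi_size < 1:
        raise ValueError("roi_size must be >= 1")
    cx, cy = center_px
    h, w = frame.shape
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise RoiOutOfBoundsError(
            f"ROI center ({cx:.1f}, {cy:.1f}) outside {w}x{h} frame"
        )
    x0, x1 = _roi_bounds(cx, roi_size, w)
    y0, y1 = _roi_bounds(cy, roi_size, h)
    window = frame.temperatures[y0:y1, x0:x1]
    return float(window.max()), int(window.size)


# ---------------------------------------------------------------------------
# cpTD


@dataclass
class RoiReading:
    name: str
    region: str
    center_px: tuple[float, float]
    max_temp_c: float
    n_valid_px: int


@dataclass
class CpTDRecord:
    """Per-frame central-peripheral temperature difference and its inputs.

    ``cptd`` is ``central_mean - peripheral_mean`` and is None (flagged via
    ``defined``) when either region has no usable landmark.
    """

    central_mean: float | None
    peripheral_mean: float | None
    cptd: float | None
    readings: list[RoiReading] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    n_central: int = 0
    n_peripheral: int = 0
    frame_id: str = ""

    @property
    def defined(self) -> bool:
        return self.cptd is not None


def compute_cptd(
    frame: ThermalFrame,
    irt_keypoints: KeypointSet,
    scheme: RegionScheme = DEFAULT_REGION_SCHEME,
    roi_size: int = DEFAULT_ROI_SIZE,
) -> CpTDRecord:
    """Extract the cpTD from a thermogram given landmarks in IRT coordinates.

    Landmarks with visibility 0 or centers outside the frame are excluded
    (and listed in the record).  Each remaining landmark contributes its ROI
    maximum; the group value is the unweighted arithmetic mean of those
    maxima, and cpTD = central mean - peripheral mean.  A region with no
    usable landmark leaves the cpTD undefined — flagged, never an exception.
    """
    readings: list[RoiReading] = []
    excluded: list[str] = []
    central_vals: list[float] = []
    peripheral_vals: list[float] = []
    for i, name in enumerate(KEYPOINT_NAMES):
        if irt_keypoints.visibility[i] < 1:
            excluded.append(name)
            continue
        center = (float(irt_keypoints.x[i]), float(irt_keypoints.y[i]))
        try:
            max_t, n_px = roi_max_temperature(frame, center, roi_size)
        except RoiOutOfBoundsError:
            excluded.append(name)
            continue
        region = scheme.region_of(name)
        readings.append(RoiReading(name, region, center, max_t, n_px))
        (central_vals if region == "central" else peripheral_vals).append(max_t)
    central_mean = float(np.mean(central_vals)) if central_vals else None
    peripheral_mean = float(np.mean(peripheral_vals)) if peripheral_vals else None
    cptd = None
    if central_mean is not None and peripheral_mean is not None:
        cptd = central_mean - peripheral_mean
    return CpTDRecord(
        central_mean=central_mean,
        peripheral_mean=peripheral_mean,
        cptd=cptd,
        readings=readings,
        excluded=excluded,
        n_central=len(central_vals),
        n_peripheral=len(peripheral_vals),
        frame_id=frame.frame_id,
    )


# ---------------------------------------------------------------------------
# Agreement statistics


def _paired(estimated, ground_truth) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray([np.nan if e is None else e for e in estimated], dtype=float)
    gt = np.asarray([np.nan if g is None else g for g in ground_truth], dtype=float)
    if est.shape != gt.shape:
        raise ValueError("estimated and ground_truth must have equal length")
    keep = np.isfinite(est) & np.isfinite(gt)
    return est[keep], gt[keep]


def cptd_error_stats(estimated, ground_truth) -> tuple[float, float]:
    """Mean absolute error and its sample SD between estimated and reference
    cpTD series.  Frames with an undefined cpTD (None/NaN) on either side are
    excluded pairwise.  SD uses the n-1 denominator (0.0 when n == 1)."""
    est, gt = _paired(estimated, ground_truth)
    if est.size == 0:
        raise ValueError("no defined cpTD pairs to compare")
    abs_err = np.abs(est - gt)
    mae = float(abs_err.mean())
    sd = float(abs_err.std(ddof=1)) if abs_err.size > 1 else 0.0
    return mae, sd


@dataclass
class BlandAltmanResult:
    """Agreement between an estimator and a reference.

    Differences are reference - estimate, so a positive mean difference
    means the estimator underestimates.  Limits of agreement are
    MD -/+ 1.96 SD.
    """

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(estimated, ground_truth) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of paired measurements (n >= 2)."""
    est, gt = _paired(estimated, ground_truth)
    if est.size < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 defined pairs")
    diffs = gt - est
    means = 0.5 * (gt + est)
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=md,
        sd_difference=sd,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        means=means,
        differences=diffs,
    )


def plot_bland_altman(result: BlandAltmanResult, ax=None, label: str = "cpTD"):
    """Render the standard Bland-Altman plot (pairwise mean on x, reference
    minus estimate on y, MD and limits of agreement as horizontal lines)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=14, alpha=0.7)
    ax.axhline(result.mean_difference, color="k", lw=1.2, label="mean difference")
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel(f"mean of reference and estimate ({label})")
    ax.set_ylabel("reference - estimate")
    ax.legend(loc="best", fontsize=8)
    return ax
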