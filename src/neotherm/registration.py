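"""Mutual-information registration between RGB and infrared-thermography
frames.

The two sensors view the scene from (nearly) the same angle but with
different optics and resolutions, so the mapping from RGB to IRT pixel
coordinates is modeled as a field-of-view crop of the RGB frame followed by
an affine transform:

    u = A @ (p - (crop_x, crop_y)) + t

with ``p`` in full-RGB pixel coordinates and ``u`` in IRT pixel
coordinates.  Because the modalities share no intensity relationship (a
colorful object can be invisible in a thermogram), alignment is scored by
the mutual information (MI) of the joint intensity histogram,

    I(X, Y) = sum_{x,y} p(x,y) log( p(x,y) / (p(x) p(y)) )

in nats, which is maximal when one image best predicts the other.  The fit
is a seeded two-stage random search (global uniform sampling, then greedy
Gaussian refinement with decaying step size) over a decomposed parameter
vector (translation, per-axis scale, rotation, crop margins) within bounds,
using a fixed budget of objective evaluations.

Coordinate convention throughout: 0-based, x = column, y = row, origin
top-left, coordinates refer to pixel centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .keypoints import KeypointSet

__all__ = [
    "RegistrationMap",
    "JointHistogram",
    "OptimizerSettings",
    "DegenerateImageError",
    "to_grayscale",
    "warp_to_irt",
    "joint_histogram",
    "mutual_information",
    "marginal_entropies",
    "registration_objective",
    "fit_registration",
    "transform_points",
    "transform_keypoints",
    "point_transform_error",
    "PointErrorStats",
    "px_to_mm",
]


class DegenerateImageError(ValueError):
    """Registration input carries no usable intensity structure."""


class OverlapError(RuntimeError):
    """No candidate reached the required overlap fraction."""


@dataclass
class RegistrationMap:
    """Cropped-RGB -> IRT mapping: affine entries plus symmetric crop margins.

    ``affine`` is the 2x3 matrix [[a, b, tx], [c, d, ty]] applied to
    crop-corrected coordinates; ``crop_x``/``crop_y`` are the pixel margins
    removed from each left/right (top/bottom) border of the full RGB frame
    before the affine applies.
    """

    affine: np.ndarray
    crop_x: float = 0.0
    crop_y: float = 0.0

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float).reshape(2, 3)
        if abs(self.det) < 1e-12:
            raise ValueError("affine part is not invertible (zero determinant)")
        if self.crop_x < 0 or self.crop_y < 0:
            raise ValueError("crop margins must be >= 0")

    @property
    def det(self) -> float:
        a, b, _, c, d, _ = self.affine.ravel()
        return a * d - b * c

    @classmethod
    def identity(cls) -> "RegistrationMap":
        return cls(affine=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(cls, tx: float, ty: float, sx: float, sy: float,
                    theta_deg: float, crop_x: float = 0.0,
                    crop_y: float = 0.0) -> "RegistrationMap":
        """Build from the decomposed search space: rotation(theta) composed
        with per-axis scaling, then translation."""
        th = math.radians(theta_deg)
        a = sx * math.cos(th)
        b = -sy * math.sin(th)
        c = sx * math.sin(th)
        d = sy * math.cos(th)
        return cls(affine=np.array([[a, b, tx], [c, d, ty]]),
                   crop_x=crop_x, crop_y=crop_y)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) full-RGB (x, y) points into IRT coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        shifted = pts - np.array([self.crop_x, self.crop_y])
        A = self.affine[:, :2]
        t = self.affine[:, 2]
        return shifted @ A.T + t

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) IRT (x, y) points back to full-RGB coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        A = self.affine[:, :2]
        t = self.affine[:, 2]
        src = np.linalg.solve(A, (pts - t).T).T
        return src + np.array([self.crop_x, self.crop_y])

    def validate_for_frame(self, rgb_size: tuple[int, int]) -> None:
        w, h = rgb_size
        if self.crop_x >= w / 2 or self.crop_y >= h / 2:
            raise ValueError(
                f"crop margins ({self.crop_x}, {self.crop_y}) exceed half the "
                f"RGB frame {w}x{h}"
            )

    def to_dict(self, **meta) -> dict:
        a, b, tx, c, d, ty = self.affine.ravel()
        out = {"affine": [a, b, tx, c, d, ty],
               "crop_x": float(self.crop_x), "crop_y": float(self.crop_y)}
        out.update(meta)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationMap":
        a, b, tx, c, d2, ty = d["affine"]
        return cls(affine=np.array([[a, b, tx], [c, d2, ty]]),
                   crop_x=d.get("crop_x", 0.0), crop_y=d.get("crop_y", 0.0))

    def save(self, path: str | Path, **meta) -> None:
        Path(path).write_text(json.dumps(self.to_dict(**meta), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RegistrationMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance of an 8-bit 3-channel image, rounded
    half-to-even to uint8."""
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    lum = (0.299 * img[..., 0].astype(float)
           + 0.587 * img[..., 1].astype(float)
           + 0.114 * img[..., 2].astype(float))
    return np.rint(lum).astype(np.uint8)


def warp_to_irt(
    image: np.ndarray,
    rmap: RegistrationMap,
    irt_size: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a full-RGB-frame image onto the IRT grid under a map.

    Inverse mapping with bilinear interpolation: for every IRT pixel the
    source location in the (internally crop-corrected) RGB frame is
    evaluated.  Returns the warped image and a validity mask that is True
    where the source lies inside the cropped-RGB bounds.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = to_grayscale(img).astype(float)
    h_rgb, w_rgb = img.shape
    w_irt, h_irt = irt_size
    rmap.validate_for_frame((w_rgb, h_rgb))
    uu, vv = np.meshgrid(np.arange(w_irt, dtype=float),
                         np.arange(h_irt, dtype=float))
    grid = np.stack([uu.ravel(), vv.ravel()], axis=1)
    src = rmap.apply_inverse(grid)  # full-RGB coordinates
    sx = src[:, 0].reshape(h_irt, w_irt)
    sy = src[:, 1].reshape(h_irt, w_irt)
    mask = ((sx >= rmap.crop_x) & (sx <= w_rgb - 1 - rmap.crop_x)
            & (sy >= rmap.crop_y) & (sy <= h_rgb - 1 - rmap.crop_y))
    warped = ndimage.map_coordinates(img, [sy, sx], order=1, mode="constant",
                                     cval=0.0)
    warped[~mask] = 0.0
    return warped, mask


@dataclass
class JointHistogram:
    """Joint intensity histogram of two equally-shaped images over a mask."""

    counts: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    n: int
    overlap_fraction: float = 1.0

    def transpose(self) -> "JointHistogram":
        return JointHistogram(self.counts.T, self.edges_b, self.edges_a,
                              self.n, self.overlap_fraction)


def joint_histogram(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 64,
) -> JointHistogram:
    """Joint 2-D histogram with equal-width bins spanning each image's
    min-max over the mask."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no pixels to histogram")
    av, bv = a[mask], b[mask]

    def _edges(vals: np.ndarray) -> np.ndarray:
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            hi = lo + 1.0  # constant image: a single occupied bin
        return np.linspace(lo, hi, bins + 1)

    ea, eb = _edges(av), _edges(bv)
    counts, _, _ = np.histogram2d(av, bv, bins=[ea, eb])
    return JointHistogram(
        counts=counts.astype(np.int64), edges_a=ea, edges_b=eb,
        n=int(av.size), overlap_fraction=float(mask.mean()),
    )


def mutual_information(h: JointHistogram) -> float:
    """Mutual information of a joint histogram in nats (0 log 0 = 0)."""
    if h.n <= 0:
        raise ValueError("histogram is empty")
    pxy = h.counts.astype(float) / h.n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pxy > 0, pxy / (px * py), 1.0)
        terms = np.where(pxy > 0, pxy * np.log(ratio), 0.0)
    return float(terms.sum())


def marginal_entropies(h: JointHistogram) -> tuple[float, float]:
    """Shannon entropies (nats) of the two marginal distributions."""
    pxy = h.counts.astype(float) / h.n
    ents = []
    for axis in (1, 0):
        p = pxy.sum(axis=axis)
        p = p[p > 0]
        ents.append(float(-(p * np.log(p)).sum()))
    return ents[0], ents[1]


# ---------------------------------------------------------------------------
# Optimization

PARAM_NAMES = ("tx", "ty", "sx", "sy", "theta_deg", "crop_x", "crop_y")


def default_bounds(rgb_size: tuple[int, int] | None = None) -> dict[str, tuple[float, float]]:
    """Search bounds for the decomposed parameters.

    Scales center near the typical IRT/RGB sensor-size ratio (~0.6);
    rotation is limited to +/-15 deg because both cameras share a rig; crop
    margins are capped below half the frame.
    """
    crop_x_hi, crop_y_hi = 400.0, 400.0
    if rgb_size is not None:
        w, h = rgb_size
        crop_x_hi = min(crop_x_hi, w / 2 - 1)
        crop_y_hi = min(crop_y_hi, h / 2 - 1)
    return {
        "tx": (-200.0, 200.0),
        "ty": (-200.0, 200.0),
        "sx": (0.3, 1.5),
        "sy": (0.3, 1.5),
        "theta_deg": (-15.0, 15.0),
        "crop_x": (0.0, crop_x_hi),
        "crop_y": (0.0, crop_y_hi),
    }


@dataclass
class OptimizerSettings:
    """Budgeted seeded random search over the registration parameters.

    ``n_evals`` objective evaluations are split into a global uniform stage
    and a local greedy Gaussian-perturbation stage around the incumbent
    whose step size decays from ``sigma_frac_initial`` to
    ``sigma_frac_final`` of each bound range.
    """

    n_evals: int = 500
    n_global: int = 150
    bounds: dict[str, tuple[float, float]] | None = None
    seed: int = 0
    min_overlap_fraction: float = 0.75
    bins: int = 64
    sigma_frac_initial: float = 0.10
    sigma_frac_final: float = 0.002
    direct_entries: bool = False  # search raw matrix entries instead of the decomposition

    def __post_init__(self) -> None:
        if self.n_evals < 1:
            raise ValueError("n_evals must be >= 1")
        if not 0.0 < self.min_overlap_fraction <= 1.0:
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not (np.isfinite(lo) and np.isfinite(hi) and hi >= lo):
                    raise ValueError(f"bound for {name} must be finite with hi >= lo")

    def resolved_bounds(self, rgb_size: tuple[int, int] | None = None):
        bounds = dict(default_bounds(rgb_size))
        if self.bounds:
            bounds.update(self.bounds)
        return bounds


def map_from_params(params, direct_entries: bool = False) -> RegistrationMap:
    p = np.asarray(params, dtype=float)
    if direct_entries:
        a, b, tx, c, d, ty, crop_x, crop_y = p
        return RegistrationMap(affine=np.array([[a, b, tx], [c, d, ty]]),
                               crop_x=crop_x, crop_y=crop_y)
    tx, ty, sx, sy, theta, crop_x, crop_y = p
    return RegistrationMap.from_params(tx, ty, sx, sy, theta, crop_x, crop_y)


def registration_objective(
    params,
    rgb_gray: np.ndarray,
    irt_image: np.ndarray,
    settings: OptimizerSettings,
) -> float:
    """Mutual information of (warped cropped-RGB, IRT) for one candidate.

    Candidates whose valid overlap falls below ``min_overlap_fraction`` are
    penalized proportionally (MI scaled by overlap/min_overlap), which
    suppresses the classic MI failure mode of spuriously high scores on tiny
    overlaps.  A non-invertible candidate scores -inf rather than raising.
    """
    try:
        rmap = map_from_params(params, settings.direct_entries)
        h_rgb, w_rgb = rgb_gray.shape[:2]
        rmap.validate_for_frame((w_rgb, h_rgb))
    except ValueError:
        return -np.inf
    h_irt, w_irt = np.asarray(irt_image).shape
    warped, mask = warp_to_irt(rgb_gray, rmap, (w_irt, h_irt))
    if not mask.any():
        return -np.inf
    hist = joint_histogram(warped, np.asarray(irt_image, dtype=float),
                           mask=mask, bins=settings.bins)
    mi = mutual_information(hist)
    if hist.overlap_fraction < settings.min_overlap_fraction:
        mi *= hist.overlap_fraction / settings.min_overlap_fraction
    return mi


def _foreground_moments(img: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Centroid and covariance of the bright foreground (above the midpoint
    of the intensity range); None when degenerate."""
    v = np.asarray(img, dtype=float)
    mask = v > 0.5 * (v.min() + v.max())
    if mask.sum() < 16:
        return None
    ys, xs = np.nonzero(mask)
    c = np.array([xs.mean(), ys.mean()])
    cov = np.cov(np.stack([xs.astype(float), ys.astype(float)]))
    if np.linalg.det(cov) <= 0:
        return None
    return c, cov


def _moment_seed_candidates(
    gray: np.ndarray, irt: np.ndarray,
    bounds: dict[str, tuple[float, float]], n_angles: int = 8,
) -> list[np.ndarray]:
    """Principal-axes pre-alignment candidates for the global stage.

    Per-axis scales come from the foreground variance ratio of the two
    images; the rotation is scanned over a small grid inside its bounds
    (the angle cannot be read robustly from second moments under
    anisotropic scaling); the translation closes each candidate so the
    foreground centroids coincide.  The crop seeds near the low end of its
    range — crop and translation are redundant for the composite map, and a
    small crop keeps the overlap large.  A classic initialization for MI
    registration, which otherwise has a narrow capture range.
    """
    m_rgb = _foreground_moments(gray)
    m_irt = _foreground_moments(irt)
    if m_rgb is None or m_irt is None:
        return []
    (c_r, C_r), (c_i, C_i) = m_rgb, m_irt
    sx = math.sqrt(C_i[0, 0] / C_r[0, 0])
    sy = math.sqrt(C_i[1, 1] / C_r[1, 1])
    s_lo, s_hi = bounds["sx"]
    sx = float(np.clip(sx, s_lo, s_hi))
    sy = float(np.clip(sy, *bounds["sy"]))
    cx = bounds["crop_x"][0] + 0.1 * (bounds["crop_x"][1] - bounds["crop_x"][0])
    cy = bounds["crop_y"][0] + 0.1 * (bounds["crop_y"][1] - bounds["crop_y"][0])
    t_lo, t_hi = bounds["theta_deg"]
    cands = []
    for th in np.linspace(0.93 * t_lo, 0.93 * t_hi, n_angles):
        r = math.radians(th)
        A = np.array([[sx * math.cos(r), -sy * math.sin(r)],
                      [sx * math.sin(r), sy * math.cos(r)]])
        t = c_i - A @ (c_r - np.array([cx, cy]))
        cands.append(np.array([t[0], t[1], sx, sy, th, cx, cy]))
    return cands


def fit_registration(
    rgb_image: np.ndarray,
    irt_image: np.ndarray,
    settings: OptimizerSettings | None = None,
) -> tuple[RegistrationMap, float, list[tuple[int, np.ndarray, float]]]:
    """Estimate the RGB -> IRT map by maximizing mutual information.

    Seeded two-stage search with a fixed budget of ``settings.n_evals``
    objective evaluations.  The global stage scores principal-axes
    (moment-based) seed candidates, uniform random draws within bounds, and
    Gaussian draws around the best seed; the local stage refines the
    incumbent's translation/scale/rotation with Nelder-Mead (explicit
    per-parameter initial simplex, candidates clipped to bounds) while the
    crop margins stay at their stage-one values — crop and translation are
    redundant for the composite point mapping, so the crop only needs to be
    roughly right for the overlap mask.  Returns the best map, its
    (penalized) MI, and the trace of accepted incumbents as
    (evaluation index, params, score).  Deterministic given the seed.
    """
    settings = settings or OptimizerSettings()
    rgb = np.asarray(rgb_image)
    gray = to_grayscale(rgb).astype(float) if rgb.ndim == 3 else rgb.astype(float)
    irt = np.asarray(irt_image, dtype=float)
    if gray.max() == gray.min():
        raise DegenerateImageError("RGB image is constant; nothing to register")
    if irt.max() == irt.min():
        raise DegenerateImageError("IRT image is constant; nothing to register")
    h_rgb, w_rgb = gray.shape
    bounds = settings.resolved_bounds((w_rgb, h_rgb))
    names = PARAM_NAMES
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    rng = np.random.default_rng(settings.seed)
    span = hi - lo

    if settings.direct_entries:
        return _fit_direct_entries(gray, irt, settings, rng)

    best_params: np.ndarray | None = None
    best_score = -np.inf
    trace: list[tuple[int, np.ndarray, float]] = []
    evals = 0

    def consider(params: np.ndarray) -> float:
        nonlocal best_params, best_score, evals
        score = registration_objective(params, gray, irt, settings)
        evals += 1
        if score > best_score:
            best_score, best_params = score, params.copy()
            trace.append((evals, params.copy(), score))
        return score

    # --- global stage: moment seeds, uniform draws, draws around the seed
    n_global = min(settings.n_global, settings.n_evals)
    seeds = _moment_seed_candidates(gray, irt, bounds)[:n_global]
    seed_best: np.ndarray | None = None
    seed_best_score = -np.inf
    for p in seeds:
        p = np.clip(p, lo, hi)
        s = consider(p)
        if s > seed_best_score:
            seed_best_score, seed_best = s, p
    n_uniform = min(40, max(0, n_global - len(seeds)))
    for _ in range(n_uniform):
        consider(rng.uniform(lo, hi))
    seed_sigma = np.array([0.05, 0.05, 0.042, 0.042, 0.067, 0.15, 0.15]) * span
    center = seed_best if seed_best is not None else (
        best_params if best_params is not None else 0.5 * (lo + hi))
    for _ in range(n_global - evals):
        consider(np.clip(center + rng.normal(0.0, 1.0, len(names)) * seed_sigma,
                         lo, hi))

    if best_params is None or not np.isfinite(best_score) or best_score <= 0:
        raise OverlapError(
            "no candidate reached min_overlap_fraction="
            f"{settings.min_overlap_fraction} with positive mutual "
            "information; widen bounds or lower the threshold"
        )

    # --- local stage: Nelder-Mead over (tx, ty, sx, sy, theta), crop fixed
    n_local = settings.n_evals - evals
    if n_local > 6:
        from scipy import optimize

        crop = best_params[5:].copy()

        def negobj(q: np.ndarray) -> float:
            p = np.clip(np.concatenate([q, crop]), lo, hi)
            return -consider(p)

        q0 = best_params[:5]
        sim_scale = np.array([0.0375, 0.0375, 0.033, 0.033, 0.05]) * span[:5]
        simplex = np.vstack([q0] + [q0 + np.eye(5)[i] * sim_scale[i]
                                    for i in range(5)])
        optimize.minimize(
            negobj, q0, method="Nelder-Mead",
            options={"maxfev": n_local, "xatol": 1e-4, "fatol": 1e-10,
                     "initial_simplex": simplex, "adaptive": True},
        )

    return map_from_params(best_params, settings.direct_entries), best_score, trace


def _fit_direct_entries(gray, irt, settings, rng):
    """Fallback search over raw matrix entries plus crops: uniform sampling
    then greedy Gaussian refinement with geometrically decaying step."""
    h_rgb, w_rgb = gray.shape
    s = max(irt.shape[1] / w_rgb, 0.1)
    lo = np.array([0.2 * s, -0.5, -200.0, -0.5, 0.2 * s, -200.0, 0.0, 0.0])
    hi = np.array([2.5 * s, 0.5, 200.0, 0.5, 2.5 * s, 200.0,
                   w_rgb / 2 - 1, h_rgb / 2 - 1])
    best_p, best_s = None, -np.inf
    trace = []
    n_global = min(settings.n_global, settings.n_evals)
    evals = 0
    for _ in range(n_global):
        p = rng.uniform(lo, hi)
        sc = registration_objective(p, gray, irt, settings)
        evals += 1
        if sc > best_s:
            best_s, best_p = sc, p
            trace.append((evals, p.copy(), sc))
    if best_p is None or not np.isfinite(best_s):
        raise OverlapError(
            f"no candidate reached min_overlap_fraction={settings.min_overlap_fraction}")
    span = hi - lo
    n_local = settings.n_evals - n_global
    decay = (settings.sigma_frac_final / settings.sigma_frac_initial) ** (
        1.0 / max(n_local - 1, 1))
    sigma = settings.sigma_frac_initial
    for _ in range(n_local):
        step = rng.normal(0.0, sigma, len(lo)) * span
        active = rng.random(len(lo)) < 0.5
        if not active.any():
            active[rng.integers(len(lo))] = True
        c = np.clip(best_p + np.where(active, step, 0.0), lo, hi)
        sc = registration_objective(c, gray, irt, settings)
        evals += 1
        if sc > best_s:
            best_s, best_p = sc, c
            trace.append((evals, c.copy(), sc))
        sigma *= decay
    return map_from_params(best_p, True), best_s, trace


# ---------------------------------------------------------------------------
# Point transfer and its evaluation


def transform_points(points: np.ndarray, rmap: RegistrationMap) -> np.ndarray:
    """Map (N, 2) points from full-RGB into IRT pixel coordinates
    (exact, no rounding)."""
    return rmap.apply(points)


def transform_keypoints(
    kps: KeypointSet,
    rmap: RegistrationMap,
    irt_size: tuple[int, int] | None = None,
) -> tuple[KeypointSet, np.ndarray]:
    """Transform a keypoint set into IRT coordinates.

    Visibility flags pass through unchanged.  Returns the transformed set
    and a boolean out-of-bounds mask (all False when ``irt_size`` is
    omitted); out-of-frame points are flagged but still returned.
    """
    out = kps.copy()
    mapped = rmap.apply(kps.coords())
    out.x, out.y = mapped[:, 0].copy(), mapped[:, 1].copy()
    out.scale_area = kps.scale_area * abs(rmap.det)
    oob = np.zeros(len(out.x), dtype=bool)
    if irt_size is not None:
        w, h = irt_size
        oob = ~((out.x >= 0) & (out.x <= w - 1) & (out.y >= 0) & (out.y <= h - 1))
    return out, oob


@dataclass
class PointErrorStats:
    """Per-axis point-transfer error: MAE and SD of the absolute deviations,
    in px and mm."""

    mae_x_px: float
    mae_y_px: float
    sd_x_px: float
    sd_y_px: float
    mm_per_px: float
    n: int

    @property
    def mae_x_mm(self) -> float:
        return px_to_mm(self.mae_x_px, self.mm_per_px)

    @property
    def mae_y_mm(self) -> float:
        return px_to_mm(self.mae_y_px, self.mm_per_px)

    @property
    def sd_x_mm(self) -> float:
        return px_to_mm(self.sd_x_px, self.mm_per_px)

    @property
    def sd_y_mm(self) -> float:
        return px_to_mm(self.sd_y_px, self.mm_per_px)


def point_transform_error(
    predicted_irt_points: np.ndarray,
    gt_irt_points: np.ndarray,
    mm_per_px: float = 0.5,
) -> PointErrorStats:
    """Per-axis MAE and SD between transformed and reference IRT points.

    MAE_x is the mean of |dx| over point pairs (likewise y); the SDs are the
    sample standard deviations (n-1) of those absolute deviations, 0.0 for a
    single pair.
    """
    pred = np.atleast_2d(np.asarray(predicted_irt_points, dtype=float))
    gt = np.atleast_2d(np.asarray(gt_irt_points, dtype=float))
    if pred.shape != gt.shape or pred.shape[0] < 1:
        raise ValueError("need n >= 1 matched point pairs of equal shape")
    abs_dev = np.abs(pred - gt)
    sd = abs_dev.std(axis=0, ddof=1) if pred.shape[0] > 1 else np.zeros(2)
    return PointErrorStats(
        mae_x_px=float(abs_dev[:, 0].mean()),
        mae_y_px=float(abs_dev[:, 1].mean()),
        sd_x_px=float(sd[0]),
        sd_y_px=float(sd[1]),
        mm_per_px=mm_per_px,
        n=pred.shape[0],
    )


def px_to_mm(value_px: float, mm_per_px: float) -> float:
    """Convert a pixel distance to millimeters at a given spatial resolution
    (0.5 mm/px at the clinical ~1 m camera distance)."""
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be > 0")
    return value_px * mm_per_px
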