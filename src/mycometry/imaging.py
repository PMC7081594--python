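"""Computational trace-ring measurement (the Fiji workflow, automated).

The manual workflow this reproduces: calibrate pixel distance to
millimetres using the known Petri-dish diameter (Set Scale), superimpose
three equally spaced measurement axes originating at the edge of the
inoculation plug, and read off the distance to each day's trace along each
axis. Here the dish rim is found by a circular Hough transform (with a
manual override), each axis is sampled at sub-pixel resolution by bilinear
interpolation, and trace crossings are prominence-thresholded local minima
of the smoothed radial intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d
from scipy.signal import find_peaks, peak_widths
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import DishDetectionError, ExtractionError, GeometryError, ValidationError
from .quantify import PlateTraces
from .render import PlateImage

__all__ = [
    "CalibratedImage",
    "RayProfile",
    "MeasureConfig",
    "detect_dish",
    "calibrate_scale",
    "measure_ray_crossings",
    "extract_plate_traces",
    "calibrate_plate_image",
]


@dataclass
class CalibratedImage:
    """A grayscale image with a pixel-to-millimetre calibration."""

    pixels: np.ndarray  # 2-D float
    center_xy: tuple[float, float]  # dish centre, (x=col, y=row) pixels
    dish_diameter_px: float
    dish_diameter_mm: float = 90.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValidationError("CalibratedImage expects a 2-D grayscale array")
        h, w = self.pixels.shape
        x, y = self.center_xy
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(f"centre {self.center_xy} outside image {w}x{h}")
        if not self.dish_diameter_px > 0 or not self.dish_diameter_mm > 0:
            raise ValidationError("dish diameters must be positive")

    @property
    def mm_per_pixel(self) -> float:
        return calibrate_scale(self.dish_diameter_px, self.dish_diameter_mm)


@dataclass(frozen=True)
class MeasureConfig:
    """Knobs of the automated crossing detector.

    ``smooth_px`` is the boxcar width applied to the radial profile,
    ``prominence_frac`` the minimum peak prominence as a fraction of the
    profile's dynamic range, and ``stroke_mm`` the assumed marker width:
    minima closer than one stroke are merged into a single crossing.
    """

    step_px: float = 0.25  # sub-pixel sampling step along the ray
    smooth_px: float = 3.0
    prominence_frac: float = 0.10
    stroke_mm: float = 0.8
    start_offset_mm: float = 0.8  # skip the immediate neighbourhood of the origin
    rim_margin_mm: float = 2.0  # stop short of the rim so it is not a "crossing"
    invert: bool = False  # True for light traces on dark background


@dataclass
class RayProfile:
    """Radial intensity profile along one measurement axis."""

    angle_deg: float
    distance_mm: np.ndarray  # sample positions from the origin
    intensity: np.ndarray
    crossings_mm: list[float] = field(default_factory=list)
    mismatch: bool = False  # crossing count differs from the expected day count


def calibrate_scale(dish_diameter_px: float, dish_diameter_mm: float = 90.0) -> float:
    """mm per pixel from the dish diameter (9 cm storage dish by default)."""
    if not dish_diameter_px > 0:
        raise ValidationError(f"dish_diameter_px must be > 0, got {dish_diameter_px}")
    if not dish_diameter_mm > 0:
        raise ValidationError(f"dish_diameter_mm must be > 0, got {dish_diameter_mm}")
    return float(dish_diameter_mm) / float(dish_diameter_px)


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    p = np.asarray(pixels, dtype=float)
    if p.ndim == 3:
        p = p[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return p


def detect_dish(
    image: np.ndarray,
    radius_range_px: tuple[int, int] | None = None,
    *,
    canny_sigma: float = 2.0,
    score_threshold: float = 0.25,
    manual: tuple[tuple[float, float], float] | None = None,
) -> tuple[tuple[float, float], float]:
    """Locate the dish rim; returns ``((cx, cy), diameter_px)``.

    A circular Hough accumulator is scanned over ``radius_range_px``
    (default 30–48 % of the smaller image dimension) on a Canny edge map,
    coarsely first and then refined to 1 px. A ``manual``
    ``((cx, cy), diameter_px)`` override is returned verbatim without
    running detection, mirroring manual calibration in the original
    workflow.
    """
    if manual is not None:
        return manual
    gray = _to_gray(image)
    h, w = gray.shape
    if radius_range_px is None:
        lo = int(0.38 * min(h, w))
        hi = int(0.49 * min(h, w))
    else:
        lo, hi = int(radius_range_px[0]), int(radius_range_px[1])
    rng_span = gray.max() - gray.min()
    if rng_span == 0:
        raise DishDetectionError(
            "blank image: no edges found; supply manual calibration "
            "((cx, cy), diameter_px)"
        )
    edges = canny(gray, sigma=canny_sigma)
    if not edges.any():
        raise DishDetectionError(
            "no edges found; supply manual calibration ((cx, cy), diameter_px)"
        )

    def _best(radii: np.ndarray):
        acc = hough_circle(edges, radii)
        accums, cx, cy, rad = hough_circle_peaks(acc, radii, total_num_peaks=1)
        return float(accums[0]), float(cx[0]), float(cy[0]), int(rad[0])

    coarse_radii = np.arange(lo, hi + 1, 3)
    score, cx, cy, r = _best(coarse_radii)
    fine_radii = np.arange(max(lo, r - 3), min(hi, r + 3) + 1)
    score, cx, cy, r = _best(fine_radii)
    if score < score_threshold:
        raise DishDetectionError(
            f"best circle score {score:.3f} below threshold {score_threshold}; "
            "supply manual calibration ((cx, cy), diameter_px)"
        )
    # Canny locks onto one edge of the rim stroke; recentre the radius on the
    # stroke's darkness centre of mass so calibration is stroke-width independent
    r_ref = _refine_rim_radius(gray, (cx, cy), float(r))
    return (cx, cy), 2.0 * r_ref


def _refine_rim_radius(
    gray: np.ndarray, center: tuple[float, float], r0: float, halfwidth_px: float = 10.0
) -> float:
    """Centre of mass of rim darkness over radii ``r0 +/- halfwidth_px``."""
    cx, cy = center
    radii = np.arange(max(1.0, r0 - halfwidth_px), r0 + halfwidth_px + 0.25, 0.25)
    ang = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    cols = cx + radii[:, None] * np.cos(ang)[None, :]
    rows = cy + radii[:, None] * np.sin(ang)[None, :]
    prof = map_coordinates(gray, [rows, cols], order=1, mode="nearest").mean(axis=1)
    darkness = prof.max() - prof
    weights = np.where(darkness > 0.5 * darkness.max(), darkness, 0.0)
    if weights.sum() == 0:
        return r0
    return float((radii * weights).sum() / weights.sum())


def measure_ray_crossings(
    image: CalibratedImage,
    origin_xy: tuple[float, float],
    angle_deg: float,
    expected_n: int | None = None,
    config: MeasureConfig | None = None,
) -> RayProfile:
    """Detect trace crossings along one ray from ``origin_xy``.

    The ray is sampled every ``step_px`` pixels by bilinear interpolation
    from the origin out to just inside the dish rim; crossings are the
    prominence-thresholded minima of the boxcar-smoothed profile, merged
    when closer than the marker stroke width, reported in mm from the
    origin in ascending order.
    """
    cfg = config or MeasureConfig()
    gray = _to_gray(image.pixels)
    mmpp = image.mm_per_pixel
    h, w = gray.shape
    ox, oy = origin_xy
    cx, cy = image.center_xy
    a = np.deg2rad(angle_deg)
    ux, uy = np.cos(a), -np.sin(a)  # y axis points down in pixel space

    # distance along the ray at which it meets the dish rim
    rel = np.array([ox - cx, oy - cy])
    b = rel[0] * ux + rel[1] * uy
    c0 = rel @ rel - (image.dish_diameter_px / 2.0) ** 2
    disc = b * b - c0
    if disc <= 0:
        raise GeometryError("origin outside the dish")
    t_rim = -b + np.sqrt(disc)
    t_stop = t_rim - cfg.rim_margin_mm / mmpp
    end_x, end_y = ox + t_rim * ux, oy + t_rim * uy
    if not (0 <= end_x < w and 0 <= end_y < h):
        raise GeometryError(
            f"ray at {angle_deg:.1f} deg exits the image before the dish rim"
        )

    t0 = cfg.start_offset_mm / mmpp
    if t_stop <= t0:
        raise GeometryError("no room between origin and dish rim to measure")
    t = np.arange(t0, t_stop, cfg.step_px)
    cols = ox + t * ux
    rows = oy + t * uy
    profile = map_coordinates(gray, [rows, cols], order=1, mode="nearest")

    signal = -profile if not cfg.invert else profile.copy()
    size = max(1, int(round(cfg.smooth_px / cfg.step_px)))
    smooth = uniform_filter1d(signal, size=size)
    dyn = np.ptp(smooth)
    crossings: list[float] = []
    if dyn > 0:
        peaks, props = find_peaks(smooth, prominence=cfg.prominence_frac * dyn)
        if peaks.size:
            # a marker stroke gives a flat-bottomed dip, so the deepest noisy
            # sample wanders across the bottom; the midpoint of the dip's
            # half-prominence width is the stable sub-pixel estimate
            _, _, left_ips, right_ips = peak_widths(smooth, peaks, rel_height=0.5)
            centres = (left_ips + right_ips) / 2.0
            pos_mm = (t0 + centres * cfg.step_px) * mmpp
            prom = props["prominences"]
            # merge minima closer than one marker stroke: keep the deepest
            merged: list[tuple[float, float]] = [(pos_mm[0], prom[0])]
            for p, pr in zip(pos_mm[1:], prom[1:]):
                if p - merged[-1][0] < cfg.stroke_mm:
                    if pr > merged[-1][1]:
                        merged[-1] = (p, pr)
                else:
                    merged.append((p, pr))
            crossings = [m[0] for m in merged]
    mismatch = expected_n is not None and len(crossings) != expected_n
    return RayProfile(
        angle_deg=float(angle_deg),
        distance_mm=t * mmpp,
        intensity=profile,
        crossings_mm=crossings,
        mismatch=bool(mismatch),
    )


def extract_plate_traces(
    image: CalibratedImage,
    n_days: int,
    *,
    plate_key: tuple = ("", "", "", "", ""),
    n_axes: int = 3,
    reference_angle_deg: float = 0.0,
    plug_radius_mm: float = 2.5,
    config: MeasureConfig | None = None,
) -> PlateTraces:
    """Measure all axes of a plate and emit a :class:`PlateTraces`.

    Axes sit at ``reference_angle_deg + k * 360/n_axes``; each ray starts at
    the plug edge (``plug_radius_mm`` from the centre along the axis), so
    crossing distances are radii from the plug edge, day ``d`` being the
    d-th crossing. An axis whose crossing count differs from ``n_days``
    keeps its partial measurements but is flagged in ``axis_flags``; if no
    axis yields any crossing the extraction fails.
    """
    if n_days < 1:
        raise ValidationError(f"n_days must be >= 1, got {n_days}")
    mmpp = image.mm_per_pixel
    cx, cy = image.center_xy
    observations: list[tuple[str, float, float]] = []
    axis_flags: dict[str, bool] = {}
    total = 0
    for k in range(n_axes):
        angle = reference_angle_deg + k * 360.0 / n_axes
        a = np.deg2rad(angle)
        origin = (cx + plug_radius_mm / mmpp * np.cos(a),
                  cy - plug_radius_mm / mmpp * np.sin(a))
        ray = measure_ray_crossings(image, origin, angle, expected_n=n_days,
                                    config=config)
        axis_id = f"axis{k + 1}"
        axis_flags[axis_id] = ray.mismatch
        for day, radius in enumerate(ray.crossings_mm[:n_days], start=1):
            observations.append((axis_id, float(day), float(radius)))
        total += len(ray.crossings_mm)
    if total == 0:
        raise ExtractionError("no trace crossings detected on any axis")
    return PlateTraces(*[str(p) for p in plate_key], observations=observations,
                       axis_flags=axis_flags)


def calibrate_plate_image(
    image: PlateImage, auto_detect: bool = False, **detect_kwargs
) -> CalibratedImage:
    """CalibratedImage from a rendered plate, via metadata or Hough detection."""
    if auto_detect:
        center, diameter_px = detect_dish(image.pixels, **detect_kwargs)
    else:
        center, diameter_px = image.center_xy, image.dish_diameter_px
    return CalibratedImage(
        pixels=_to_gray(image.pixels),
        center_xy=center,
        dish_diameter_px=diameter_px,
        dish_diameter_mm=image.dish_diameter_mm,
    )
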