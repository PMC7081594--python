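"""Synthetic traced-plate photograph renderer with ground truth.

Draws what a top-down photo of a marker-traced Petri dish looks like after
an n-day experiment: a dark dish rim, and one dark closed curve per day at
that day's leading-edge radius. Each ring passes exactly through the traced
radii on the measurement axes (between axes the radius is interpolated,
optionally with a wavy perturbation that vanishes on the axes), so ray
measurements along the axes can be validated against stored ground truth.

Angles are degrees counter-clockwise from the image +x direction (y axis
points down in pixel space). Radii are millimetres from the plug edge, as
everywhere in this package; rings are drawn at ``plug_radius + radius``
from the dish centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import GeometryError, ValidationError
from .quantify import PlateTraces

__all__ = ["RenderConfig", "PlateImage", "render_plate_image", "save_plate_image",
           "load_plate_image"]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters.

    Gray levels are in [0, 1] (0 = black). ``waviness_cycles`` is rounded
    to a multiple of the axis count so the perturbation is zero on every
    measurement axis and ground truth stays exact along the rays.
    """

    mm_per_pixel: float = 0.1
    margin_mm: float = 4.0  # background border around the dish
    stroke_mm: float = 0.8  # marker line width
    rim_stroke_mm: float = 1.2
    waviness_mm: float = 0.0  # amplitude of the ring perturbation
    waviness_cycles: int = 6
    background: float = 0.85
    ink: float = 0.15
    noise_sd: float = 0.01  # additive Gaussian pixel noise (gray-level units)
    seed: int = 0

    def validate(self) -> None:
        if not self.mm_per_pixel > 0:
            raise ValidationError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        if not self.stroke_mm > 0:
            raise ValidationError(
                f"stroke_mm must be > 0 (a zero-width marker draws nothing), "
                f"got {self.stroke_mm}"
            )
        if not self.rim_stroke_mm > 0:
            raise ValidationError(f"rim_stroke_mm must be > 0, got {self.rim_stroke_mm}")
        if self.waviness_mm < 0 or self.noise_sd < 0:
            raise ValidationError("waviness_mm and noise_sd must be >= 0")


@dataclass
class PlateImage:
    """A rendered (or loaded) plate photo plus its geometry and ground truth."""

    pixels: np.ndarray  # 2-D float, gray levels in [0, 1]
    center_xy: tuple[float, float]  # pixels, (x=col, y=row)
    dish_diameter_px: float
    dish_diameter_mm: float
    mm_per_pixel: float
    plug_radius_mm: float
    axis_angles_deg: list[float]
    true_radii_mm: dict[str, dict[int, float]] = field(default_factory=dict)
    plate_key: tuple | None = None

    @property
    def dish_radius_mm(self) -> float:
        return self.dish_diameter_mm / 2.0


def _axis_angles(n_axes: int, reference_angle_deg: float) -> list[float]:
    return [(reference_angle_deg + k * 360.0 / n_axes) % 360.0 for k in range(n_axes)]


def _ring_radius_of_theta(
    theta: np.ndarray,
    axis_radii_px: np.ndarray,
    wav_amp_px: float,
    wav_cycles: int,
    ref_angle_rad: float,
) -> np.ndarray:
    """Smooth closed-curve radius through the per-axis anchors, plus waviness.

    The anchors sit at ``ref_angle + 2*pi*j/n`` in axis order; band-limited
    trigonometric interpolation (FFT of the anchor radii) passes through
    them exactly and is C-infinity in between — a marker trace has no
    corners, and a kink at an anchor would bias the radial intensity
    profile exactly where the measurement rays cross.
    """
    n = axis_radii_px.size
    delta = theta - ref_angle_rad
    coef = np.fft.fft(axis_radii_px) / n
    base = np.full_like(theta, coef[0].real)
    for k in range(1, n // 2 + 1):
        if 2 * k == n:  # Nyquist bin of an even anchor count
            base = base + coef[k].real * np.cos(k * delta)
        else:
            base = base + 2 * (coef[k].real * np.cos(k * delta)
                               - coef[k].imag * np.sin(k * delta))
    if wav_amp_px > 0 and wav_cycles > 0:
        base = base + wav_amp_px * np.sin(wav_cycles * delta)
    return base


def render_plate_image(
    traces: PlateTraces,
    render: RenderConfig | None = None,
    *,
    plug_radius_mm: float = 2.5,
    dish_diameter_mm: float = 90.0,
    reference_angle_deg: float = 0.0,
) -> PlateImage:
    """Render a traced plate to a grayscale image with stored ground truth."""
    render = render or RenderConfig()
    render.validate()
    dish_radius_mm = dish_diameter_mm / 2.0

    axes = sorted({o[0] for o in traces.observations})
    days = sorted({int(o[1]) for o in traces.observations})
    if not axes or not days:
        raise ValidationError("traces contain no observations to render")
    radii: dict[str, dict[int, float]] = {a: {} for a in axes}
    for axis, day, radius in traces.observations:
        radii[axis][int(day)] = float(radius)
    for a in axes:
        missing = [d for d in days if d not in radii[a]]
        if missing:
            raise ValidationError(f"axis {a} is missing radii for days {missing}")
        vals = [radii[a][d] for d in days]
        if any(np.diff(vals) <= 0):
            raise ValidationError(f"axis {a}: ring radii must increase strictly with day")

    worst = max(max(radii[a].values()) for a in axes)
    if plug_radius_mm + worst + render.stroke_mm / 2 >= dish_radius_mm:
        raise GeometryError(
            f"largest ring ({plug_radius_mm + worst:.1f} mm from centre) reaches "
            f"the dish rim ({dish_radius_mm:.1f} mm)"
        )

    mmpp = render.mm_per_pixel
    side_px = int(np.ceil(2 * (dish_radius_mm + render.margin_mm) / mmpp))
    c = (side_px - 1) / 2.0
    yy, xx = np.mgrid[0:side_px, 0:side_px].astype(float)
    dx = xx - c
    dy = -(yy - c)  # y up for angle math
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    # round waviness cycles up to a multiple of the axis count: zero on axes
    n_axes = len(axes)
    cycles = int(np.ceil(render.waviness_cycles / n_axes)) * n_axes \
        if render.waviness_mm > 0 else 0

    alpha = np.zeros_like(dist)  # ink coverage, max over strokes
    stroke_px = render.stroke_mm / mmpp

    for d in days:
        ring_r_px = _ring_radius_of_theta(
            theta,
            np.array([(plug_radius_mm + radii[a][d]) / mmpp for a in axes]),
            render.waviness_mm / mmpp,
            cycles,
            np.deg2rad(reference_angle_deg),
        )
        cov = np.clip(stroke_px / 2.0 + 0.5 - np.abs(dist - ring_r_px), 0.0, 1.0)
        np.maximum(alpha, cov, out=alpha)

    rim_px = dish_radius_mm / mmpp
    rim_cov = np.clip(
        render.rim_stroke_mm / mmpp / 2.0 + 0.5 - np.abs(dist - rim_px), 0.0, 1.0
    )
    np.maximum(alpha, rim_cov, out=alpha)

    img = render.background * (1 - alpha) + render.ink * alpha
    if render.noise_sd > 0:
        rng = np.random.default_rng(render.seed)
        img = img + render.noise_sd * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)

    return PlateImage(
        pixels=img,
        center_xy=(c, c),
        dish_diameter_px=2 * rim_px,
        dish_diameter_mm=dish_diameter_mm,
        mm_per_pixel=mmpp,
        plug_radius_mm=plug_radius_mm,
        axis_angles_deg=_axis_angles(n_axes, reference_angle_deg),
        true_radii_mm={a: dict(radii[a]) for a in axes},
        plate_key=traces.key if traces.lab_id else None,
    )


def save_plate_image(image: PlateImage, path: str | Path) -> Path:
    """Write the pixels as 8-bit PNG and the geometry/ground truth as a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, (image.pixels * 255).round().astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "center_xy": list(image.center_xy),
        "dish_diameter_px": image.dish_diameter_px,
        "dish_diameter_mm": image.dish_diameter_mm,
        "mm_per_pixel": image.mm_per_pixel,
        "plug_radius_mm": image.plug_radius_mm,
        "axis_angles_deg": image.axis_angles_deg,
        "true_radii_mm": {a: {str(d): r for d, r in v.items()}
                          for a, v in image.true_radii_mm.items()},
        "plate_key": list(image.plate_key) if image.plate_key else None,
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def load_plate_image(path: str | Path) -> PlateImage:
    """Load a PNG written by :func:`save_plate_image` (sidecar JSON required)."""
    path = Path(path)
    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:  # RGB(A) -> luminance
        pixels = pixels[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    pixels = pixels / 255.0
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PlateImage(
        pixels=pixels,
        center_xy=tuple(meta["center_xy"]),
        dish_diameter_px=float(meta["dish_diameter_px"]),
        dish_diameter_mm=float(meta["dish_diameter_mm"]),
        mm_per_pixel=float(meta["mm_per_pixel"]),
        plug_radius_mm=float(meta["plug_radius_mm"]),
        axis_angles_deg=list(meta["axis_angles_deg"]),
        true_radii_mm={a: {int(d): float(r) for d, r in v.items()}
                       for a, v in meta["true_radii_mm"].items()},
        plate_key=tuple(meta["plate_key"]) if meta.get("plate_key") else None,
    )
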