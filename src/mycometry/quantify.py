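"""Colony radial extension rates from daily leading-edge traces.

A plate's extension rate is the slope of a single ordinary least-squares
regression of radius (mm) on time (days), pooling the daily trace points
from all measurement axes of that plate. The slope in mm/day is the primary
performance measure; rates under 2 mm/day are flagged as being at the limit
of quantification of the marker-trace technique (flagged, never dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContaminatedPlateError, InsufficientDataError, ValidationError
from .simulate import PLATE_KEY

__all__ = [
    "PlateTraces",
    "ExtensionRate",
    "fit_extension_rate",
    "flag_below_loq",
    "fit_all_plates",
    "summarize_rates",
    "DEFAULT_LOQ_MM_PER_DAY",
]

#: Rates below this are at the limit of quantification of the trace assay.
DEFAULT_LOQ_MM_PER_DAY = 2.0


@dataclass
class PlateTraces:
    """Per-plate daily leading-edge radii along the measurement axes.

    ``observations`` is a list of ``(axis_id, day, radius_mm)`` tuples with
    radii measured from the inoculation-plug edge. Days are positive (first
    trace at 24 h = day 1); fractional days are accepted. ``axis_flags``
    records per-axis quality problems from image extraction (True = the
    crossing count did not match the expected number of days).
    """

    lab_id: str
    organism: str
    substrate: str
    substrate_source: str
    plate_id: str
    observations: list[tuple[str, float, float]] = field(default_factory=list)
    contaminated: bool = False
    axis_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.lab_id, self.organism, self.substrate,
                self.substrate_source, self.plate_id)

    def validate(self) -> None:
        for axis, day, radius in self.observations:
            if not day > 0:
                raise ValidationError(f"day must be positive, got {day} on axis {axis}")
            if radius < 0:
                raise ValidationError(f"radius must be >= 0, got {radius} on axis {axis}")
        self._warn_non_monotone()

    def _warn_non_monotone(self) -> None:
        frame = self.to_frame()
        for axis, grp in frame.groupby("axis_id"):
            r = grp.sort_values("day")["radius_mm"].to_numpy()
            if np.any(np.diff(r) < 0):
                warnings.warn(
                    f"plate {self.key}: radii decrease with day along axis {axis} "
                    "(marker traces can wobble; points kept)",
                    stacklevel=3,
                )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.observations, columns=["axis_id", "day", "radius_mm"])
        if (frame["day"] % 1 == 0).all():
            frame["day"] = frame["day"].astype(int)
        for col, val in zip(PLATE_KEY, self.key):
            frame[col] = val
        frame["contaminated"] = int(self.contaminated)
        return frame[PLATE_KEY + ["contaminated", "axis_id", "day", "radius_mm"]]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PlateTraces":
        keys = frame[PLATE_KEY].drop_duplicates()
        if len(keys) != 1:
            raise ValidationError("frame contains more than one plate")
        key = keys.iloc[0]
        contaminated = bool(frame["contaminated"].astype(int).any()) \
            if "contaminated" in frame else False
        obs = [
            (str(r.axis_id), float(r.day), float(r.radius_mm))
            for r in frame.itertuples()
        ]
        return cls(*[str(k) for k in key], observations=obs, contaminated=contaminated)


@dataclass(frozen=True)
class ExtensionRate:
    """Fitted radial extension rate with OLS diagnostics."""

    key: tuple
    rate: float  # slope, mm/day
    intercept: float  # mm
    n_points: int
    r_squared: float
    stderr: float  # standard error of the slope
    below_loq: bool

    def as_dict(self) -> dict:
        d = dict(zip(PLATE_KEY, self.key))
        d.update(
            rate=self.rate,
            intercept=self.intercept,
            n_points=self.n_points,
            r_squared=self.r_squared,
            stderr=self.stderr,
            below_loq=self.below_loq,
        )
        return d


def flag_below_loq(rate: float, threshold: float = DEFAULT_LOQ_MM_PER_DAY) -> bool:
    """Strict comparison: True iff ``rate < threshold``. Rates are never dropped."""
    if not threshold > 0:
        raise ValidationError(f"loq threshold must be > 0, got {threshold}")
    return bool(rate < threshold)


def fit_extension_rate(
    plate: PlateTraces, loq_threshold: float = DEFAULT_LOQ_MM_PER_DAY
) -> ExtensionRate:
    """Pooled-axis OLS of radius on day for one plate.

    All axes' daily points enter a single regression with intercept; the
    slope is the radial extension rate. The intercept is fitted rather than
    pinned at zero because plug placement and marker width introduce small
    offsets. Missing axis/day points are simply absent (unbalanced OLS).
    """
    if plate.contaminated:
        raise ContaminatedPlateError(
            f"plate {plate.key} is contamination-flagged; it must be excluded, not fitted"
        )
    plate.validate()
    if not plate.observations:
        raise InsufficientDataError(f"plate {plate.key}: no observations")
    day = np.array([o[1] for o in plate.observations], dtype=float)
    radius = np.array([o[2] for o in plate.observations], dtype=float)
    if np.unique(day).size < 2:
        raise InsufficientDataError(
            f"plate {plate.key}: need >= 2 distinct days to fit a slope, "
            f"got {np.unique(day).size}"
        )
    with warnings.catch_warnings():
        # linregress warns on zero y-variance; r² is nan there and kept as such
        warnings.simplefilter("ignore", category=RuntimeWarning)
        fit = stats.linregress(day, radius)
        r_squared = float(fit.rvalue**2)
    return ExtensionRate(
        key=plate.key,
        rate=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(day.size),
        r_squared=r_squared,
        stderr=float(fit.stderr),
        below_loq=flag_below_loq(float(fit.slope), loq_threshold),
    )


def fit_all_plates(
    traces: pd.DataFrame, loq_threshold: float = DEFAULT_LOQ_MM_PER_DAY
) -> pd.DataFrame:
    """Fit every non-contaminated plate in a trace table.

    Returns a rate table with one row per plate: the plate key columns plus
    ``rate, intercept, n_points, r_squared, stderr, below_loq``.
    Contamination-flagged plates are excluded (the exclusion is recorded in
    the ``attrs['excluded_contaminated']`` list of the result).
    """
    excluded: list[tuple] = []
    rows: list[dict] = []
    for key, grp in traces.groupby(PLATE_KEY, sort=True):
        if "contaminated" in grp and grp["contaminated"].astype(int).any():
            excluded.append(key)
            continue
        plate = PlateTraces.from_frame(grp)
        rows.append(fit_extension_rate(plate, loq_threshold).as_dict())
    table = pd.DataFrame(rows)
    table.attrs["excluded_contaminated"] = excluded
    return table


def summarize_rates(rates: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """Group means, sample SDs (ddof=1) and plate counts of extension rates.

    ``rates`` is a rate table from :func:`fit_all_plates` (contaminated
    plates are already excluded there). Single-plate groups get SD = NaN;
    groups whose every plate is below the limit of quantification carry
    ``all_below_loq = True`` so reports can mark them as at the measurement
    limit.
    """
    missing = [k for k in group_keys if k not in rates.columns]
    if missing:
        raise ValidationError(f"unknown group keys: {missing}")
    grouped = rates.groupby(group_keys, sort=True)
    out = grouped.agg(
        mean_rate=("rate", "mean"),
        sd_rate=("rate", lambda v: v.std(ddof=1)),
        n=("rate", "size"),
    )
    if "below_loq" in rates.columns:
        out["all_below_loq"] = grouped["below_loq"].agg("all")
    return out.reset_index()
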