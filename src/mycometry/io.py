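"""Trace CSV schema, run configuration, and ground-truth sidecars.

The trace CSV is the study's exchange format: one row per (plate, axis,
day), UTF-8, header required::

    lab_id,organism,substrate,substrate_source,plate_id,contaminated,axis_id,day,radius_mm

``contaminated`` is 0/1 and marks plates that must be excluded from fitting
and summaries; ``day`` is a positive integer (trace at 24 h intervals);
``radius_mm`` is a non-negative decimal measured from the plug edge.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError
from .simulate import GroundTruth, SimulationConfig

__all__ = [
    "TRACE_COLUMNS",
    "read_traces_csv",
    "write_traces_csv",
    "write_ground_truth",
    "RunConfig",
]

TRACE_COLUMNS = [
    "lab_id",
    "organism",
    "substrate",
    "substrate_source",
    "plate_id",
    "contaminated",
    "axis_id",
    "day",
    "radius_mm",
]

_KEY_COLUMNS = TRACE_COLUMNS[:5]


def write_traces_csv(traces: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise SchemaError(f"trace table missing columns: {missing}")
    traces[TRACE_COLUMNS].to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a trace CSV.

    All row-level violations are collected and reported together with their
    1-based file line numbers (header is line 1); nothing is silently
    dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRACE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    errors: list[str] = []
    out = raw.copy()

    def _line(i: int) -> int:
        return i + 2  # header occupies line 1

    day = pd.to_numeric(raw["day"], errors="coerce")
    for i in day.index[day.isna()]:
        errors.append(f"line {_line(i)}: day {raw.at[i, 'day']!r} is not a number")
    ok = day.notna()
    bad_day = ok & ((day % 1 != 0) | (day < 1))
    for i in day.index[bad_day]:
        errors.append(f"line {_line(i)}: day {raw.at[i, 'day']!r} must be a positive integer")

    radius = pd.to_numeric(raw["radius_mm"], errors="coerce")
    for i in radius.index[radius.isna()]:
        errors.append(
            f"line {_line(i)}: radius_mm {raw.at[i, 'radius_mm']!r} is not a number"
        )
    for i in radius.index[radius.notna() & (radius < 0)]:
        errors.append(f"line {_line(i)}: radius_mm {raw.at[i, 'radius_mm']!r} is negative")

    contaminated = pd.to_numeric(raw["contaminated"], errors="coerce")
    bad_c = contaminated.isna() | ~contaminated.isin([0, 1])
    for i in contaminated.index[bad_c]:
        errors.append(
            f"line {_line(i)}: contaminated {raw.at[i, 'contaminated']!r} must be 0 or 1"
        )

    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))

    out["day"] = day.astype(int)
    out["radius_mm"] = radius.astype(float)
    out["contaminated"] = contaminated.astype(int)
    return out[TRACE_COLUMNS]


def write_ground_truth(truth: GroundTruth, csv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    """Per-plate true rates as CSV; lab multipliers + true REUs as JSON sidecar."""
    csv_path = Path(csv_path)
    frame = truth.rates_frame()
    frame["saturated"] = [
        int(tuple(k) in truth.saturated_plates)
        for k in frame[_KEY_COLUMNS].itertuples(index=False)
    ]
    frame.to_csv(csv_path, index=False)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    payload = {
        "lab_multiplier": truth.lab_multiplier,
        "true_reu": {f"{o}|{s}": v for (o, s), v in truth.true_reu.items()},
    }
    Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML.

    Defaults mirror the standard assay: *G. lucidum* on locally-sourced
    reference substrate as the REU reference, a 2 mm/day limit of
    quantification, alpha = 0.05, three axes starting at 0 degrees, and a
    9 cm dish.
    """

    reference_organism: str = "G_lucidum"
    reference_source: str = "local"
    loq_threshold: float = 2.0
    alpha: float = 0.05
    n_axes: int = 3
    reference_angle_deg: float = 0.0
    dish_diameter_mm: float = 90.0
    detection: dict = field(default_factory=dict)  # detect_dish keyword overrides
    simulation: SimulationConfig | None = None
    seed: int = 0
    output_dir: str = "mycometry_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["organisms"] = list(sim["organisms"])
            sim["substrates"] = list(sim["substrates"])
            sim["substrate_sources"] = list(sim["substrate_sources"])
            sim["intrinsic_rate"] = dict(sim["intrinsic_rate"])
            sim["substrate_factor"] = dict(sim["substrate_factor"])
            d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            for key in ("organisms", "substrates", "substrate_sources"):
                if key in sim and sim[key] is not None:
                    sim[key] = list(sim[key])
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
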