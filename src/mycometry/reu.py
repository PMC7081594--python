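"""Relative Extension Units and interlaboratory variability metrics.

An REU is a plate's extension rate divided by the same lab's mean rate for
the reference condition — by convention *Ganoderma lucidum* on the
locally-sourced reference substrate. Because lab-specific extrinsic effects
(humidity, media preparation, tracing technique) act multiplicatively on
every rate a lab reports, they cancel in the ratio; REUs are therefore
comparable across labs even when absolute rates are not.

Variability is summarized by the coefficient of variation (sample SD over
mean) computed across labs on per-lab means, and by the percent reduction
in CV achieved by reporting REUs instead of raw rates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, MissingReferenceError

__all__ = [
    "compute_reu",
    "coefficient_of_variation",
    "cv_reduction",
    "fold_range",
    "interlab_variability",
    "DEFAULT_REFERENCE_ORGANISM",
    "DEFAULT_REFERENCE_SOURCE",
]

DEFAULT_REFERENCE_ORGANISM = "G_lucidum"
DEFAULT_REFERENCE_SOURCE = "local"


def compute_reu(
    rates: pd.DataFrame,
    reference_organism: str = DEFAULT_REFERENCE_ORGANISM,
    reference_source: str = DEFAULT_REFERENCE_SOURCE,
) -> pd.DataFrame:
    """Normalize a rate table to Relative Extension Units, per lab.

    For each lab the reference rate is the arithmetic mean of that lab's
    plate rates for ``(reference_organism, reference_source)``; every rate
    the lab reported (any organism, any source) is divided by it. REU is
    computed per plate so within-lab spread is preserved; the reference
    group's per-lab mean REU is exactly 1. Below-LOQ flags propagate.

    Raises
    ------
    MissingReferenceError
        If any lab has no reference-group plates.
    """
    is_ref = (rates["organism"] == reference_organism) & (
        rates["substrate_source"] == reference_source
    )
    ref_means = rates.loc[is_ref].groupby("lab_id")["rate"].mean()
    labs = rates["lab_id"].unique()
    missing = sorted(set(labs) - set(ref_means.index))
    if missing:
        raise MissingReferenceError(missing, (reference_organism, reference_source))
    out = rates.copy()
    out["reference_rate"] = out["lab_id"].map(ref_means)
    out["reu"] = out["rate"] / out["reference_rate"]
    out.attrs["reference"] = (reference_organism, reference_source)
    return out


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV: SD (ddof=1) divided by mean. Requires n >= 2 and mean > 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 values, got {v.size}")
    mean = v.mean()
    if not mean > 0:
        raise DomainError(f"CV undefined for non-positive mean {mean}")
    return float(v.std(ddof=1) / mean)


def cv_reduction(cv_raw: float, cv_reu: float) -> float:
    """Percent reduction in CV from REU reporting: ``100 * (1 - cv_reu/cv_raw)``.

    Negative when normalization worsens variation; returned unclamped.
    """
    if cv_raw == 0:
        raise DomainError("cv_reduction undefined when raw CV is 0")
    if cv_raw < 0 or cv_reu < 0:
        raise DomainError("CVs must be non-negative")
    return float(100.0 * (1.0 - cv_reu / cv_raw))


def fold_range(group_means: Sequence[float]) -> float:
    """Max/min ratio of group means (e.g. '7.5-fold across substrates')."""
    v = np.asarray(group_means, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"fold range needs >= 2 means, got {v.size}")
    if np.any(v <= 0):
        raise DomainError("fold range requires strictly positive means")
    return float(v.max() / v.min())


def interlab_variability(
    reu_table: pd.DataFrame,
    by: str = "organism",
    source: str | None = DEFAULT_REFERENCE_SOURCE,
    pool_plates: bool = False,
) -> pd.DataFrame:
    """Across-lab CV of raw rates and of REUs, per group, with the reduction.

    By default each lab contributes its per-lab mean (rates averaged over
    plates) and the CV is taken across labs, which is the natural metric for
    interlab agreement; ``pool_plates=True`` pools individual plates across
    labs instead. ``source`` restricts to one substrate source (None keeps
    all rows).

    Returns one row per group: ``cv_raw``, ``cv_reu`` and
    ``cv_reduction_percent``.
    """
    data = reu_table if source is None else reu_table[
        reu_table["substrate_source"] == source
    ]
    rows = []
    for group, grp in data.groupby(by, sort=True):
        if pool_plates:
            raw, reu = grp["rate"], grp["reu"]
        else:
            per_lab = grp.groupby("lab_id")[["rate", "reu"]].mean()
            raw, reu = per_lab["rate"], per_lab["reu"]
        cv_raw = coefficient_of_variation(raw)
        cv_reu = coefficient_of_variation(reu)
        rows.append(
            {
                by: group,
                "n_labs": grp["lab_id"].nunique(),
                "cv_raw": cv_raw,
                "cv_reu": cv_reu,
                "cv_reduction_percent": cv_reduction(cv_raw, cv_reu)
                if cv_raw > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
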