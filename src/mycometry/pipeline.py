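"""End-to-end analyses chaining quantification, normalization and statistics.

Three run modes mirror the three study designs the toolkit supports:

``screen``
    One lab, several organisms x substrates: rate table, per-factor group
    summaries with fold ranges, one-way ANOVA and Tukey HSD per factor, a
    Shapiro-Wilk normality report, and bar plots.
``correlate``
    Two substrate sources of the same substrate (e.g. locally-sourced vs
    centrally-provided): per-(lab, organism) mean rates paired across
    sources, OLS fit with R-squared and 95% confidence band, scatter plot.
``interlab``
    Multi-lab study: REU normalization against the reference condition,
    across-lab CVs of raw rates and REUs per organism with CV reductions,
    bar plots of both scales.

Every run writes CSV tables, PNG figures, a versioned machine-readable
``summary.json`` and a ``runlog.json`` recording the configuration, seed
and library versions; CSV/JSON outputs are byte-reproducible from the
logged config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .io import RunConfig, write_ground_truth, write_traces_csv
from .plots import bar_rates_plot, correlation_plot, reu_bars_plot
from .quantify import fit_all_plates, summarize_rates
from .reu import compute_reu, fold_range, interlab_variability
from .simulate import simulate_interlab_study
from .stats import one_way_anova, paired_mean_regression, shapiro_wilk_report, tukey_hsd

__all__ = ["run_pipeline", "SUMMARY_SCHEMA_VERSION"]

SUMMARY_SCHEMA_VERSION = "1"

MODES = ("screen", "correlate", "interlab")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=_json_default))


def _factor_tests(rates: pd.DataFrame, factor: str, alpha: float) -> dict:
    """ANOVA + Tukey across the levels of one factor, on plate-level rates."""
    levels = sorted(rates[factor].unique())
    groups = [rates.loc[rates[factor] == lv, "rate"].to_numpy() for lv in levels]
    out: dict = {"levels": levels}
    usable = [g for g in groups if g.size >= 2]
    if len(usable) >= 2 and all(g.size >= 2 for g in groups):
        anova = one_way_anova(groups)
        out["anova"] = {
            "F": anova.f_statistic,
            "p": anova.p_value,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "degenerate": anova.degenerate,
        }
        tukey = tukey_hsd(groups, alpha=alpha, labels=levels)
        out["tukey"] = tukey.to_dict(orient="records")
    else:
        out["anova"] = None
        out["tukey"] = None
    means = [g.mean() for g in groups if g.size]
    out["fold_range"] = fold_range(means) if len(means) >= 2 and min(means) > 0 else None
    return out


def run_pipeline(
    config: RunConfig,
    mode: str,
    traces: pd.DataFrame | None = None,
) -> dict:
    """Run one analysis mode; returns the JSON-serializable summary.

    ``traces`` may be a pre-loaded trace table (e.g. from
    :func:`mycometry.io.read_traces_csv`); if omitted, ``config.simulation``
    must be set and a synthetic study is generated with ``config.seed``.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if traces is None:
        if config.simulation is None:
            raise ValidationError(
                f"mode {mode!r} needs a trace table or a simulation config"
            )
        sim = config.simulation.with_seed(config.seed)
        traces, truth = simulate_interlab_study(sim)
        write_traces_csv(traces, outdir / "traces.csv")
        write_ground_truth(truth, outdir / "ground_truth.csv")

    rates = fit_all_plates(traces, loq_threshold=config.loq_threshold)
    rates.to_csv(outdir / "rates.csv", index=False)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "mode": mode,
        "n_plates_fit": int(len(rates)),
        "n_plates_excluded_contaminated": len(rates.attrs["excluded_contaminated"]),
    }

    if mode == "screen":
        summary.update(_run_screen(config, rates, outdir))
    elif mode == "correlate":
        summary.update(_run_correlate(config, rates, outdir))
    else:
        summary.update(_run_interlab(config, rates, outdir))

    _write_json(summary, outdir / "summary.json")
    _write_json(
        {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "mycometry": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
        outdir / "runlog.json",
    )
    return summary


def _run_screen(config: RunConfig, rates: pd.DataFrame, outdir: Path) -> dict:
    out: dict = {"factors": {}}
    for factor in ("organism", "substrate"):
        grp = summarize_rates(rates, [factor])
        grp.to_csv(outdir / f"summary_by_{factor}.csv", index=False)
        tests = _factor_tests(rates, factor, config.alpha)
        if "all_below_loq" in grp.columns:
            tests["groups_at_measurement_limit"] = grp.loc[
                grp["all_below_loq"], factor
            ].tolist()
        out["factors"][factor] = tests
        bar_rates_plot(grp, rates, factor, path=outdir / f"rates_by_{factor}.png",
                       loq=config.loq_threshold)
    if 3 <= len(rates) <= 5000 and rates["rate"].nunique() > 1:
        w, p = shapiro_wilk_report(rates["rate"])
        out["shapiro_wilk"] = {"W": w, "p": p}
    else:
        out["shapiro_wilk"] = None
    return out


def _run_correlate(config: RunConfig, rates: pd.DataFrame, outdir: Path) -> dict:
    sources = sorted(rates["substrate_source"].unique())
    if len(sources) != 2:
        raise ValidationError(
            f"correlate mode needs exactly 2 substrate sources, got {sources}"
        )
    x_src, y_src = sources
    if config.reference_source in sources:  # reference source on the y axis
        y_src = config.reference_source
        x_src = next(s for s in sources if s != y_src)
    g = rates.groupby(["lab_id", "organism", "substrate_source"])["rate"]
    means = g.mean().unstack("substrate_source")
    sds = g.std(ddof=1).unstack("substrate_source")
    pairs = means.dropna()
    fit = paired_mean_regression(
        pairs[x_src], pairs[y_src],
        x_sd=sds.loc[pairs.index, x_src], y_sd=sds.loc[pairs.index, y_src],
        alpha=config.alpha,
    )
    correlation_plot(
        fit,
        path=outdir / "correlation.png",
        xlabel=f"mean rate, {x_src} (mm/day)",
        ylabel=f"mean rate, {y_src} (mm/day)",
    )
    pairs.reset_index().to_csv(outdir / "paired_means.csv", index=False)
    return {
        "x_source": x_src,
        "y_source": y_src,
        "n_pairs": fit.n,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
    }


def _run_interlab(config: RunConfig, rates: pd.DataFrame, outdir: Path) -> dict:
    local = rates[rates["substrate_source"] == config.reference_source]
    if local.empty:
        raise ValidationError(
            f"no plates with substrate_source == {config.reference_source!r}"
        )
    reu_table = compute_reu(local, config.reference_organism, config.reference_source)
    reu_table.to_csv(outdir / "reu.csv", index=False)
    variability = interlab_variability(reu_table, by="organism",
                                       source=config.reference_source)
    variability.to_csv(outdir / "variability.csv", index=False)
    reu_bars_plot(reu_table, path=outdir / "reu_by_organism.png")
    org_summary = summarize_rates(local, ["organism"])
    bar_rates_plot(org_summary, local, "organism",
                   path=outdir / "rates_by_organism.png", loq=config.loq_threshold)
    return {
        "reference": [config.reference_organism, config.reference_source],
        "variability": variability.to_dict(orient="records"),
        "n_labs": int(local["lab_id"].nunique()),
    }
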