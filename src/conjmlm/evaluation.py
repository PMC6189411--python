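"""Pipeline driver and validation diagnostics.

`run_pipeline` executes the whole analysis on synthetic data — simulate,
prepare, fit the three pooled level-1 families, select one, fit per
stratum, fit the second-level g-functions, score the composite model —
and returns (optionally writes) a metrics report whose every number is
traceable to a pipeline stage. Diagnostics mirror the study's
figure-style outputs: normal-probability points of the pooled residuals,
per-stratum average rates, and prediction-vs-actual series on the
held-out weeks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import level1, level2, preprocessing, published
from .synthetic import SyntheticConfig, TruthModel, simulate_dataset


def normal_probability_points(residuals: np.ndarray, scale: bool = True) -> pd.DataFrame:
    """Ordered residuals against standard-normal quantiles.

    Quantiles are taken at plotting positions (i − ½)/n and, with
    ``scale``, multiplied by the residual standard deviation so that
    Gaussian residuals fall on the y = x diagonal. Zero-variance
    residuals give a degenerate (flagged) plot.
    """
    r = np.sort(np.asarray(residuals, dtype=float))
    n = len(r)
    if n < 3:
        raise ValueError(f"need at least 3 residuals, got {n}")
    sd = float(np.std(r, ddof=1))
    if sd == 0:
        warnings.warn("zero-variance residuals: degenerate probability plot", stacklevel=2)
        sd = 1.0 if not scale else 0.0
    q = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    theo = q * sd if scale else q
    return pd.DataFrame({"theoretical": theo, "residual": r})


def average_rate_by_stratum(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean weekly outpatient rate per (sex, age-group) stratum."""
    if observations.empty:
        raise ValueError("no observations")
    out = (
        observations.groupby(["sex", "age_group"], sort=True)["rate"]
        .mean()
        .reset_index()
        .rename(columns={"rate": "mean_rate"})
    )
    return out


def pooled_weekly_rates(observations: pd.DataFrame) -> pd.DataFrame:
    """Total counts over total population per week (the pooled response)."""
    g = observations.groupby("week", sort=True)[["count", "population"]].sum()
    return pd.DataFrame({"week": g.index, "rate": g["count"] / g["population"]}).reset_index(
        drop=True
    )


def prediction_actual_series(
    model: level2.MultiLevelModel, data: pd.DataFrame, split: pd.DataFrame
) -> pd.DataFrame:
    """Predicted vs actual rate on every held-out week, per stratum."""
    _, test_w = preprocessing.train_test_weeks(split)
    ages = [a for ages in level2.BLOCKS.values() for a in ages]
    rows = data[data["week"].isin(test_w) & data["age_group"].isin(ages)].copy()
    rows["predicted_rate"] = model.predict_frame(rows)
    return rows[["week", "sex", "age_group", "rate", "predicted_rate"]].reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.17g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(
    seed: int,
    config: SyntheticConfig | None = None,
    truth: TruthModel | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Simulate → prepare → fit level 1 → select → fit multi-level → evaluate.

    Returns the metrics report as a plain dict (floats at 17 significant
    digits when serialized); with ``outdir``, also writes the stage
    artifacts (CSV tables, g-function JSON, report JSON). Idempotent
    given the seed.
    """
    if config is None:
        config = SyntheticConfig(seed=seed)
    else:
        config.seed = seed

    env, obs = simulate_dataset(config, truth)
    env_t = preprocessing.transform_predictors(env)
    split = preprocessing.split_weeks(config.n_weeks, seed)

    pooled = pooled_weekly_rates(obs).merge(env_t, on="week")
    retained, screening = preprocessing.screen_predictors(
        pooled[["temp_c", "rh_pct", "o3_ppm"]], pooled["rate"]
    )

    fits: dict[str, level1.Level1Fit] = {}
    stats: dict[str, level1.FitStats] = {}
    for fid in level1.FAMILY_IDS:
        fits[fid], stats[fid] = level1.fit_family(fid, pooled, split)
    selected = level1.select_family(stats)

    data = obs.merge(env_t[["week", "x1", "x2", "x3"]], on="week")
    coef_table = level2.fit_per_stratum(selected, data, split)
    mlm = level2.fit_multilevel(coef_table)
    block_stats = level2.multilevel_stats(mlm, data, split)

    recon = published.reconstruct_table2()
    npp = normal_probability_points(fits[selected].residuals)
    stratum_means = average_rate_by_stratum(obs)
    pred_actual = prediction_actual_series(mlm, data, split)

    report = {
        "seed": seed,
        "n_weeks": config.n_weeks,
        "n_test_weeks": int((split["label"] == "test").sum()),
        "screening": {
            "retained": retained,
            "report": screening.to_dict(orient="records"),
        },
        "level1": {
            fid: {**{k: v for k, v in asdict(s).items() if k != "extra"},
                  "condition_number": s.extra.get("condition_number"),
                  "coefficients": fits[fid].coefficients()}
            for fid, s in stats.items()
        },
        "selected_family": selected,
        "multilevel": {
            block_id: {k: v for k, v in asdict(s).items() if k != "extra"}
            for block_id, s in block_stats.items()
        },
        "g_functions": {
            block_id: {
                name: {"form": g.form_id, "r2": g.r2, "coefficients": g.coefficients}
                for name, g in gset.items()
            }
            for block_id, gset in mlm.blocks.items()
        },
        "table2_reconstruction": {
            "n_cells": int(len(recon)),
            "n_match": int(recon["match"].sum()),
            "mismatched_cells": recon.loc[~recon["match"], ["sex", "age_group", "coefficient"]]
            .to_dict(orient="records"),
        },
        "stratum_mean_rates": stratum_means.to_dict(orient="records"),
    }
    report = _jsonable(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        env.to_csv(outdir / "environment.csv", index=False)
        obs[preprocessing.OBS_COLUMNS].to_csv(outdir / "observations.csv", index=False)
        split.to_csv(outdir / "split.csv", index=False)
        coef_table.to_frame().to_csv(outdir / "stratum_coefficients.csv", index=False)
        recon.to_csv(outdir / "table2_reconstruction.csv", index=False)
        npp.to_csv(outdir / "normal_probability_points.csv", index=False)
        pred_actual.to_csv(outdir / "prediction_vs_actual.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
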