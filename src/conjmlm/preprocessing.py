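"""Preparation of the weekly analysis dataset.

Raw inputs are (possibly hourly) environmental readings and per-stratum
outpatient counts with population denominators. This module aggregates
readings to weekly means, normalizes counts to rates, applies the
predictor transforms x1 = T + 20, x2 = RH, x3 = O₃ (so that both x1 and
x3 stay positive where log terms are used), screens candidate predictors
by the sign of their Pearson correlation with the response, and draws the
one-test-week-per-three-weeks train/test split used for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ENV_COLUMNS = ["week", "temp_c", "rh_pct", "o3_ppm"]
OBS_COLUMNS = ["week", "sex", "age_group", "count", "population"]


@dataclass(frozen=True)
class PredictorVector:
    """Transformed level-1 predictors for one week."""

    x1: float  # temperature + 20 (°C)
    x2: float  # relative humidity (%)
    x3: float  # O₃ (ppm)


def aggregate_to_weekly(records: pd.DataFrame, timestamp_col: str = "timestamp") -> pd.DataFrame:
    """Average timestamped readings into consecutive weekly means.

    ``records`` must contain ``timestamp_col`` plus the variable columns
    ``temp_c``, ``rh_pct`` and ``o3_ppm``; missing (NaN) readings are
    ignored in each mean. Weeks are calendar weeks (Monday-start) numbered
    0.. from the first week present; a week with no valid reading for any
    variable, or a wholly absent week inside the span, is an error.
    """
    if records.empty:
        raise ValueError("no environmental readings supplied")
    variables = [c for c in ("temp_c", "rh_pct", "o3_ppm") if c in records.columns]
    if not variables:
        raise ValueError("records carry none of temp_c, rh_pct, o3_ppm")
    ts = pd.to_datetime(records[timestamp_col])
    period = ts.dt.to_period("W")
    weekly = records[variables].groupby(period.values).mean()
    weekly = weekly.sort_index()
    full = pd.period_range(weekly.index[0], weekly.index[-1], freq="W")
    missing_weeks = full.difference(weekly.index)
    empty = weekly.columns[weekly.isna().any()].tolist()
    if len(missing_weeks) or empty:
        bad = [str(p) for p in missing_weeks]
        bad += [str(i) for i in weekly.index[weekly.isna().any(axis=1)]]
        raise ValueError(f"weeks without readings for {empty or 'all variables'}: {sorted(set(bad))}")
    out = weekly.reset_index(drop=True)
    out.insert(0, "week", np.arange(len(out)))
    return out


def compute_rate(count: int, population: int) -> float:
    """Outpatient rate = count / population (per person per week)."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if count > population:
        warnings.warn(
            f"count {count} exceeds population {population}; rate > 1", stacklevel=2
        )
    return count / population


def add_rates(observations: pd.DataFrame) -> pd.DataFrame:
    """Attach the exact rate column to an observations frame."""
    obs = observations.copy()
    if (obs["population"] <= 0).any():
        bad = obs.loc[obs["population"] <= 0, ["week", "sex", "age_group"]]
        raise ValueError(f"non-positive populations at:\n{bad}")
    obs["rate"] = obs["count"] / obs["population"]
    return obs


def transform_predictors(env: pd.DataFrame, require_log_domain: bool = True) -> pd.DataFrame:
    """Map weekly environment to the model predictors x1, x2, x3.

    x1 = temp_c + 20 keeps winter temperatures positive; x2 and x3 are the
    humidity and ozone series unchanged. With ``require_log_domain`` the
    function rejects weeks where a log-family design would be undefined
    (x1 <= 0 or x3 <= 0).
    """
    out = env.copy()
    out["x1"] = out["temp_c"] + 20.0
    out["x2"] = out["rh_pct"]
    out["x3"] = out["o3_ppm"]
    if require_log_domain:
        bad = out.loc[(out["x1"] <= 0) | (out["x3"] <= 0), "week"].tolist()
        if bad:
            raise ValueError(f"x1 or x3 non-positive (log domain) in weeks {bad}")
    return out


def screen_predictors(candidates: pd.DataFrame, response: pd.Series) -> tuple[list[str], pd.DataFrame]:
    """Drop candidate predictors that do not correlate positively with the response.

    Mirrors the screening step in which PM₁₀, NO₂ and SO₂ were removed for
    their negative correlations with the outpatient rate. Returns the
    retained column names and a report with Pearson r and r² per
    candidate (the study quotes the O₃ association both as r and as R²,
    so both are emitted, labeled).
    """
    if len(response) != len(candidates):
        raise ValueError("candidates and response must have equal length")
    if len(response) < 3:
        raise ValueError("need at least 3 weeks to screen predictors")
    y = np.asarray(response, dtype=float)
    rows = []
    retained = []
    for name in candidates.columns:
        x = np.asarray(candidates[name], dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero-variance series for {name}; removed", stacklevel=2)
            rows.append({"candidate": name, "pearson_r": np.nan, "r_squared": np.nan, "retained": False})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        keep = r > 0
        rows.append({"candidate": name, "pearson_r": r, "r_squared": r * r, "retained": keep})
        if keep:
            retained.append(name)
    return retained, pd.DataFrame(rows)


def split_weeks(n_weeks: int, seed: int) -> pd.DataFrame:
    """Label one random week per consecutive 3-week block as the test week.

    Replicates the validation protocol: over 156 weeks, one week in every
    three (52 weeks total) is held out for the out-of-sample test and the
    remaining two thirds are used for fitting. A trailing partial block
    (n_weeks mod 3 != 0) contributes no test week, so the test count is
    always floor(n_weeks / 3).
    """
    if n_weeks < 3:
        raise ValueError(f"need at least 3 weeks to split, got {n_weeks}")
    rng = np.random.default_rng(seed)
    labels = np.full(n_weeks, "train", dtype=object)
    n_blocks = n_weeks // 3
    offsets = rng.integers(0, 3, size=n_blocks)
    labels[np.arange(n_blocks) * 3 + offsets] = "test"
    return pd.DataFrame({"week": np.arange(n_weeks), "label": labels})


def train_test_weeks(split: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (train week indices, test week indices) from a split frame."""
    train = split.loc[split["label"] == "train", "week"].to_numpy()
    test = split.loc[split["label"] == "test", "week"].to_numpy()
    return train, test
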