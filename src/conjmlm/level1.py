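"""Level-1 regression families for the weekly outpatient rate.

Three nested-by-construction families relate the weekly rate y to the
transformed predictors x1 (temperature + 20 °C), x2 (relative humidity %)
and x3 (O₃ ppm):

* M1 (linear):        y = β₀ + β₁₁x₁ + β₂₁x₂ + β₃₁x₃ + ε
* M2 (linear + log):  adds β₁₂ln x₁, β₂₂ln x₂, β₃₂ln x₃
* M3 (linear + exp):  adds β₁₂eˣ¹, β₂₂eˣ², β₃₂eˣ³

Fits are ordinary least squares (via statsmodels, which solves through an
orthogonalizing pseudo-inverse rather than raw normal equations — the
exp-family design is severely ill-conditioned, e.g. e^58 ≈ 1.5e25 for a
typical humidity). The design's condition number is recorded on every
fit. Families are compared by in-sample adjusted R² together with the
out-of-sample R² on the held-out one-week-in-three test set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

FAMILY_IDS = ("M1", "M2", "M3")

#: design column names per family, in the fixed β order
FAMILY_COLUMNS: dict[str, tuple[str, ...]] = {
    "M1": ("beta0", "beta11", "beta21", "beta31"),
    "M2": ("beta0", "beta11", "beta12", "beta21", "beta22", "beta31", "beta32"),
    "M3": ("beta0", "beta11", "beta12", "beta21", "beta22", "beta31", "beta32"),
}

ALL_COEF_NAMES = FAMILY_COLUMNS["M2"]


@dataclass
class Level1Fit:
    """An OLS fit of one model family."""

    family_id: str
    params: np.ndarray  # estimated coefficients, design-column order
    bse: np.ndarray  # standard errors, same order
    n_obs: int
    residuals: np.ndarray
    condition_number: float

    @property
    def n_params(self) -> int:
        return len(self.params)

    def coefficients(self) -> dict[str, float]:
        """Full 7-name coefficient map; terms absent from the family are 0."""
        est = dict(zip(FAMILY_COLUMNS[self.family_id], self.params))
        return {name: est.get(name, 0.0) for name in ALL_COEF_NAMES}

    def predict(self, design: np.ndarray) -> np.ndarray:
        return np.asarray(design) @ self.params


@dataclass
class FitStats:
    """In-sample (and optionally out-of-sample) goodness of fit."""

    r2: float
    adj_r2: float
    f_statistic: float
    p_value: float
    r2_out: float | None = None
    n_train: int = 0
    n_test: int = 0
    extra: dict = field(default_factory=dict)


def family_terms(family_id: str, x1: float, x2: float, x3: float) -> dict[str, float]:
    """Term values per coefficient name for one predictor row.

    The linear family carries only the four linear terms; the log and exp
    families add ln(x)/exp(x) companions. Log terms require x1 > 0 and
    x3 > 0.
    """
    if family_id == "M1":
        return {"beta0": 1.0, "beta11": x1, "beta21": x2, "beta31": x3}
    if family_id == "M2":
        if x1 <= 0 or x3 <= 0:
            raise ValueError(f"log terms need x1 > 0 and x3 > 0, got x1={x1}, x3={x3}")
        return {
            "beta0": 1.0,
            "beta11": x1,
            "beta12": math.log(x1),
            "beta21": x2,
            "beta22": math.log(x2),
            "beta31": x3,
            "beta32": math.log(x3),
        }
    if family_id == "M3":
        return {
            "beta0": 1.0,
            "beta11": x1,
            "beta12": math.exp(x1),
            "beta21": x2,
            "beta22": math.exp(x2),
            "beta31": x3,
            "beta32": math.exp(x3),
        }
    raise ValueError(f"unknown family {family_id!r}")


def build_design(family_id: str, predictors: pd.DataFrame) -> np.ndarray:
    """Design matrix for a family over weekly predictor rows (x1, x2, x3).

    Columns follow the fixed β order of ``FAMILY_COLUMNS``. Log terms are
    the natural logarithm; exp terms exponentiate the raw predictor
    values.
    """
    if family_id not in FAMILY_IDS:
        raise ValueError(f"unknown family {family_id!r}")
    x1 = np.asarray(predictors["x1"], dtype=float)
    x2 = np.asarray(predictors["x2"], dtype=float)
    x3 = np.asarray(predictors["x3"], dtype=float)
    ones = np.ones_like(x1)
    if family_id == "M1":
        return np.column_stack([ones, x1, x2, x3])
    if family_id == "M2":
        for name, v in (("x1", x1), ("x2", x2), ("x3", x3)):
            if np.any(v <= 0):
                weeks = np.flatnonzero(v <= 0)
                if "week" in predictors.columns:
                    weeks = predictors["week"].to_numpy()[weeks]
                raise ValueError(f"ln({name}) undefined in weeks {weeks.tolist()}")
        return np.column_stack(
            [ones, x1, np.log(x1), x2, np.log(x2), x3, np.log(x3)]
        )
    return np.column_stack([ones, x1, np.exp(x1), x2, np.exp(x2), x3, np.exp(x3)])


def fit_least_squares(design: np.ndarray, y: np.ndarray, family_id: str = "M2") -> Level1Fit:
    """Ordinary least squares via an orthogonalization-based solver.

    Raises on rank-deficient designs, naming the offending columns; the
    condition number of the design is attached to the returned fit so
    ill-conditioning (expected for the exp family) is visible.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    # column equilibration: the exp family mixes column scales by tens of
    # orders of magnitude (e.g. e^58 for a typical humidity), which breaks
    # any rank test or pseudo-inverse cutoff relative to the largest
    # singular value.  Scaling each column to unit norm is an exact OLS
    # reparameterization and keeps the solve well-posed.
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        names = FAMILY_COLUMNS.get(family_id, tuple(f"col{i}" for i in range(p)))
        zero = [names[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"all-zero design columns: {zero}")
    scaled = design / norms
    rank = np.linalg.matrix_rank(scaled)
    if rank < p:
        _, _, pivots = scipy.linalg.qr(scaled, mode="economic", pivoting=True)
        names = FAMILY_COLUMNS.get(family_id, tuple(f"col{i}" for i in range(p)))
        collinear = [names[i] if i < len(names) else f"col{i}" for i in sorted(pivots[rank:])]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, scaled).fit()
    params = np.asarray(res.params) / norms
    return Level1Fit(
        family_id=family_id,
        params=params,
        bse=np.asarray(res.bse) / norms,
        n_obs=n,
        residuals=y - design @ params,
        condition_number=float(np.linalg.cond(scaled)),
    )


def fit_stats(fit: Level1Fit, y_train: np.ndarray) -> FitStats:
    """In-sample R², adjusted R², and the overall-F test of the fit.

    adj R² = 1 − (1 − R²)(n − 1)/(n − p) with the intercept counted in p;
    the F statistic has (p − 1, n − p) degrees of freedom. A constant
    response (SST = 0) leaves R² undefined and is flagged with NaNs.
    """
    y = np.asarray(y_train, dtype=float)
    n, p = fit.n_obs, fit.n_params
    sse = float(fit.residuals @ fit.residuals)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn("constant response: R² undefined", stacklevel=2)
        return FitStats(np.nan, np.nan, np.nan, np.nan, n_train=n)
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if sse == 0:
        return FitStats(1.0, 1.0, np.inf, 0.0, n_train=n)
    f_stat = ((sst - sse) / (p - 1)) / (sse / (n - p))
    p_value = float(scipy.stats.f.sf(f_stat, p - 1, n - p))
    return FitStats(r2, adj, f_stat, p_value, n_train=n)


def out_of_sample_r2(
    fit: Level1Fit,
    test_design: np.ndarray,
    y_test: np.ndarray,
    center: str = "test",
    y_train_mean: float | None = None,
) -> float:
    """Out-of-sample R² = 1 − Σ(y − ŷ)² / Σ(y − ȳ)² on held-out weeks.

    ``center`` selects the mean the total sum of squares is taken about:
    the test-set mean (default) or, with ``center='train'``, the training
    mean supplied as ``y_train_mean``. Can be negative when the model
    predicts worse than the centering constant.
    """
    y = np.asarray(y_test, dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    yhat = fit.predict(test_design)
    if center == "test":
        ybar = y.mean()
    elif center == "train":
        if y_train_mean is None:
            raise ValueError("center='train' requires y_train_mean")
        ybar = y_train_mean
    else:
        raise ValueError(f"unknown centering {center!r}")
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0:
        raise ValueError("degenerate test set: zero variance about the centering mean")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def fit_family(
    family_id: str,
    data: pd.DataFrame,
    split: pd.DataFrame,
    response: str = "rate",
) -> tuple[Level1Fit, FitStats]:
    """Fit one family on the training weeks of ``data`` and score both samples.

    ``data`` carries one row per week with columns week, x1, x2, x3 and
    the response; ``split`` labels each week train or test.
    """
    merged = data.merge(split, on="week", validate="many_to_one")
    train = merged[merged["label"] == "train"]
    test = merged[merged["label"] == "test"]
    design = build_design(family_id, train)
    y_train = train[response].to_numpy(dtype=float)
    fit = fit_least_squares(design, y_train, family_id)
    stats = fit_stats(fit, y_train)
    if len(test):
        stats.r2_out = out_of_sample_r2(
            fit, build_design(family_id, test), test[response].to_numpy(dtype=float)
        )
        stats.n_test = len(test)
    stats.extra["condition_number"] = fit.condition_number
    return fit, stats


def select_family(results: dict[str, FitStats]) -> str:
    """Pick the best family from per-family fit statistics.

    A family that is at least as good as every other on both in-sample
    adjusted R² and out-of-sample R² wins; if no family dominates, the
    highest out-of-sample R² wins. Exact ties go to the family with fewer
    terms, then to the lower family index.
    """
    if len(results) < 2:
        raise ValueError("need at least two fitted families to select")

    def sort_key(fid: str) -> tuple[int, int]:
        return (len(FAMILY_COLUMNS[fid]), FAMILY_IDS.index(fid))

    fids = sorted(results, key=sort_key)
    best_adj = max(results[f].adj_r2 for f in fids)
    best_out = max(results[f].r2_out for f in fids)
    dominators = [
        f
        for f in fids
        if results[f].adj_r2 >= best_adj and results[f].r2_out >= best_out
    ]
    if dominators:
        return dominators[0]
    return max(fids, key=lambda f: (results[f].r2_out, -sort_key(f)[0], -sort_key(f)[1]))
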