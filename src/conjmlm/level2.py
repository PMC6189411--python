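"""Second-level modelling of the stratum coefficients over sex and age.

The two-stage procedure: fit the chosen level-1 family separately in each
of the 18 (sex, age-group) strata, then regress every level-1 coefficient
β on sex and age across strata. Each coefficient's second-level function
g(sex, age) is chosen among three candidate forms

    sex + age + sex·age
    sex + ln(age) + sex·ln(age)
    sex + exp(age) + sex·exp(age)

by highest R² over the block's strata; the intercept function g₀ uses the
full form with all age terms (where the block has enough strata to
estimate it). Two composite models are assembled by age block — ages 1–2
and ages 3–7; age groups 8 and 9 are excluded because their pattern over
the week differs from the younger groups. Age enters the forms as the
integer group code 1–9.

The ages-1-2 block has 4 strata and the candidate forms 4 parameters, so
its fits are saturated: the fitted g interpolates the stratum
coefficients exactly, and the composite block-1 prediction equals the
stratum-wise level-1 prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import published
from .level1 import ALL_COEF_NAMES, FitStats, Level1Fit, family_terms, fit_family
from .preprocessing import train_test_weeks

#: term lists per second-level form, in design-column order
FORM_TERMS: dict[str, tuple[str, ...]] = {
    "linear": ("1", "sex", "age", "sex_age"),
    "log": ("1", "sex", "ln_age", "sex_ln_age"),
    "exp": ("1", "sex", "exp_age", "sex_exp_age"),
    "g0-full": ("1", "sex", "age", "ln_age", "exp_age", "sex_age", "sex_ln_age", "sex_exp_age"),
}

#: selection preference on exact R² ties
CANDIDATE_FORMS = ("linear", "log", "exp")

BLOCKS: dict[str, tuple[int, ...]] = {
    "ages-1-2": (1, 2),
    "ages-3-7": (3, 4, 5, 6, 7),
}

EXCLUDED_AGES = (8, 9)


def _term_value(term: str, sex: float, age: float) -> float:
    values = {
        "1": 1.0,
        "sex": sex,
        "age": age,
        "ln_age": math.log(age),
        "exp_age": math.exp(age),
        "sex_age": sex * age,
        "sex_ln_age": sex * math.log(age),
        "sex_exp_age": sex * math.exp(age),
    }
    return values[term]


@dataclass
class CoefficientTable:
    """Per-(sex, age) level-1 coefficient vectors, all from one family."""

    family_id: str
    coefficients: dict[tuple[int, int], dict[str, float]]
    fits: dict[tuple[int, int], Level1Fit] = field(default_factory=dict)
    stats: dict[tuple[int, int], FitStats] = field(default_factory=dict)

    @property
    def strata(self) -> list[tuple[int, int]]:
        return sorted(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": s, "age_group": a, **self.coefficients[(s, a)]}
            for (s, a) in self.strata
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_published_table2(cls) -> "CoefficientTable":
        return cls(
            family_id="M2",
            coefficients={k: dict(v) for k, v in published.TABLE2.items()},
        )


@dataclass
class GFunction:
    """A fitted second-level function g(sex, age) for one level-1 coefficient."""

    target: str
    form_id: str
    coefficients: dict[str, float]
    block: tuple[int, ...]
    r2: float


def evaluate_g(g: GFunction, sex: int, age: int) -> float:
    """Evaluate g(sex, age); (sex, age) must lie in the g's age block."""
    if age not in g.block:
        raise ValueError(f"age group {age} outside block {g.block} of g[{g.target}]")
    return sum(c * _term_value(t, sex, age) for t, c in g.coefficients.items())


def fit_per_stratum(
    family_id: str,
    data: pd.DataFrame,
    split: pd.DataFrame,
    response: str = "rate",
) -> CoefficientTable:
    """Fit the level-1 family independently in every (sex, age) stratum.

    ``data`` holds one row per week × stratum with predictor columns
    x1..x3 and the response; every stratum uses the same family and the
    same train/test split.
    """
    table = CoefficientTable(family_id=family_id, coefficients={})
    for (sex, age), group in data.groupby(["sex", "age_group"], sort=True):
        key = (int(sex), int(age))
        try:
            fit, stats = fit_family(family_id, group, split, response=response)
        except ValueError as err:
            raise ValueError(f"stratum (sex={key[0]}, age={key[1]}): {err}") from err
        table.fits[key] = fit
        table.stats[key] = stats
        table.coefficients[key] = fit.coefficients()
    return table


def _form_design(form_id: str, points: list[tuple[int, int]]) -> np.ndarray:
    terms = FORM_TERMS[form_id]
    return np.array([[_term_value(t, s, a) for t in terms] for s, a in points])


def fit_g(
    coef_table: CoefficientTable,
    target: str,
    block: tuple[int, ...],
    candidates: tuple[str, ...] | None = None,
) -> GFunction:
    """Fit and select the second-level function for one coefficient.

    Each candidate form is fit by unweighted OLS over the block's strata
    with the stratum's β value as response; the highest-R² candidate wins
    (ties go to the earlier candidate, i.e. linear before log before
    exp). For the intercept β₀ the full form is used without selection,
    falling back to the plain linear form where the block has too few
    strata to estimate it (the ages-1-2 block: two age levels cannot
    separate age, ln(age) and exp(age)).

    A saturated fit (as many parameters as strata) is the exact
    interpolation and reports R² = 1 by convention.
    """
    points = [(s, a) for (s, a) in coef_table.strata if a in block]
    if not points:
        raise ValueError(f"no strata in block {block}")
    beta = np.array([coef_table.coefficients[p][target] for p in points])

    if target == "beta0" and candidates is None:
        full = FORM_TERMS["g0-full"]
        forms = ("g0-full",) if len(points) >= len(full) else ("linear",)
    else:
        forms = candidates or CANDIDATE_FORMS

    best: GFunction | None = None
    for form_id in forms:
        terms = FORM_TERMS[form_id]
        design = _form_design(form_id, points)
        n, p = design.shape
        if n < p:
            raise ValueError(
                f"form {form_id!r} has {p} parameters but block {block} only {n} strata"
            )
        if n == p:
            coefs = np.linalg.solve(design, beta)
            r2 = 1.0
        else:
            coefs, _, _, _ = np.linalg.lstsq(design, beta, rcond=None)
            sse = float(np.sum((beta - design @ coefs) ** 2))
            sst = float(np.sum((beta - beta.mean()) ** 2))
            # constant β across strata leaves SST at round-off scale; the
            # exact fit through the intercept then counts as R² = 1
            tiny = 1e-20 * max(1.0, float(beta @ beta))
            if sst > tiny:
                r2 = 1.0 - sse / sst
            else:
                r2 = 1.0 if sse <= tiny else 0.0
        g = GFunction(target, form_id, dict(zip(terms, coefs)), tuple(block), r2)
        if best is None or g.r2 > best.r2:
            best = g
    assert best is not None
    return best


@dataclass
class MultiLevelModel:
    """Composite two-stage predictor with per-age-block g-function sets."""

    family_id: str
    blocks: dict[str, dict[str, GFunction]]
    excluded_ages: tuple[int, ...] = EXCLUDED_AGES

    def block_for(self, age: int) -> str:
        if age in self.excluded_ages:
            raise ValueError(
                f"age group {age} was excluded from the multi-level model"
            )
        for block_id, ages in BLOCKS.items():
            if age in ages:
                return block_id
        raise ValueError(f"age group {age} not covered by any block")

    def coefficients_at(self, sex: int, age: int) -> dict[str, float]:
        gset = self.blocks[self.block_for(age)]
        return {name: evaluate_g(gset[name], sex, age) for name in ALL_COEF_NAMES}

    def predict(self, sex: int, age: int, x1: float, x2: float, x3: float) -> float:
        """y = Σᵢⱼ gᵢⱼ(sex, age) · termᵢⱼ(x), terms per the level-1 family.

        For the linear+log family: y = g₀ + g₁₁x₁ + g₁₂ln x₁ + g₂₁x₂ +
        g₂₂ln x₂ + g₃₁x₃ + g₃₂ln x₃.
        """
        terms = family_terms(self.family_id, x1, x2, x3)
        c = self.coefficients_at(sex, age)
        return sum(c[name] * value for name, value in terms.items())

    def predict_frame(self, data: pd.DataFrame) -> np.ndarray:
        return np.array(
            [
                self.predict(int(r.sex), int(r.age_group), r.x1, r.x2, r.x3)
                for r in data.itertuples()
            ]
        )

    @classmethod
    def from_published(cls) -> "MultiLevelModel":
        """The printed multi-level models, wrapped as GFunction sets."""
        blocks: dict[str, dict[str, GFunction]] = {}
        for model_id, block_id in (("mlm-ages-1-2", "ages-1-2"), ("mlm-ages-3-7", "ages-3-7")):
            ages, gset = published.MULTILEVEL[model_id]
            blocks[block_id] = {
                name: GFunction(
                    target=name,
                    form_id="published",
                    coefficients=dict(terms),
                    block=tuple(sorted(ages)),
                    r2=float("nan"),
                )
                for name, terms in gset.items()
            }
        return cls(family_id="M2", blocks=blocks)


def assemble_multilevel(
    g_sets: dict[str, dict[str, GFunction]], family_id: str = "M2"
) -> MultiLevelModel:
    """Assemble a composite model from complete per-block g-function sets."""
    for block_id, gset in g_sets.items():
        missing = [n for n in ALL_COEF_NAMES if n not in gset]
        if missing:
            raise ValueError(f"block {block_id!r} missing g-functions for {missing}")
    return MultiLevelModel(family_id=family_id, blocks=dict(g_sets))


def fit_multilevel(coef_table: CoefficientTable) -> MultiLevelModel:
    """Fit all g-functions over both age blocks and assemble the composite."""
    g_sets = {
        block_id: {
            name: fit_g(coef_table, name, ages) for name in ALL_COEF_NAMES
        }
        for block_id, ages in BLOCKS.items()
    }
    return assemble_multilevel(g_sets, coef_table.family_id)


def multilevel_stats(
    model: MultiLevelModel,
    data: pd.DataFrame,
    split: pd.DataFrame,
    response: str = "rate",
) -> dict[str, FitStats]:
    """Pooled goodness of fit of the composite model, per age block.

    In-sample statistics pool all (week × stratum) training rows of the
    block; p counts every second-level coefficient of the block's
    g-functions. Out-of-sample R² is computed on the held-out weeks about
    the test rows' mean.
    """
    import scipy.stats

    train_w, test_w = train_test_weeks(split)
    out: dict[str, FitStats] = {}
    for block_id, ages in BLOCKS.items():
        rows = data[data["age_group"].isin(ages)]
        if rows.empty:
            raise ValueError(f"no observations for block {block_id!r}")
        train = rows[rows["week"].isin(train_w)]
        test = rows[rows["week"].isin(test_w)]
        y = train[response].to_numpy(dtype=float)
        yhat = model.predict_frame(train)
        n = len(y)
        p = sum(len(g.coefficients) for g in model.blocks[block_id].values())
        sse = float(np.sum((y - yhat) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / sst
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
        if sse > 0:
            f_stat = ((sst - sse) / (p - 1)) / (sse / (n - p))
            p_value = float(scipy.stats.f.sf(f_stat, p - 1, n - p))
        else:
            f_stat, p_value = np.inf, 0.0
        stats = FitStats(r2, adj, f_stat, p_value, n_train=n)
        if len(test):
            yt = test[response].to_numpy(dtype=float)
            yth = model.predict_frame(test)
            stats.r2_out = 1.0 - float(np.sum((yt - yth) ** 2)) / float(
                np.sum((yt - yt.mean()) ** 2)
            )
            stats.n_test = len(test)
        out[block_id] = stats
    return out
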