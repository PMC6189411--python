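"""Published conjunctivitis outpatient-rate models.

This module hard-codes the coefficient sets of the published Seoul
conjunctivitis study: the three pooled level-1 regressions (linear,
linear+log, linear+exponential), the per-(sex, age) stratum fits of the
linear+log family, and the two multi-level (two-stage) models whose
second-level g-functions map (sex, age) to level-1 coefficients — one for
age groups 1–2 and one for age groups 3–7 (age groups 8 and 9 were
excluded from the second-level fits).

Coefficients are stored as the exact decimal strings that appear in print
and parsed once at import time; all predictions are plain arithmetic
evaluations of the printed equations.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

#: canonical coefficient order of the linear+log (7-term) family
COEF_NAMES = ("beta0", "beta11", "beta12", "beta21", "beta22", "beta31", "beta32")

#: pooled level-1 models (Table-1 layout); absent terms are structural zeros
TABLE1: dict[str, dict[str, float]] = {
    model_id: {name: float(value) for name, value in coefs.items()}
    for model_id, coefs in {
        "table1-M1": {
            "beta0": "2.1E-05",
            "beta11": "3.6E-07",
            "beta21": "-7.8E-08",
            "beta31": "1.2E-04",
        },
        "table1-M2": {
            "beta0": "8.1E-05",
            "beta11": "7.6E-07",
            "beta12": "-1.1E-05",
            "beta21": "1.6E-07",
            "beta22": "-1.5E-05",
            "beta31": "2.6E-04",
            "beta32": "-2.4E-06",
        },
        "table1-M3": {
            "beta0": "-4.2E-03",
            "beta11": "3.6E-07",
            "beta12": "1.7E-28",
            "beta21": "-7.0E-08",
            "beta22": "-4.7E-45",
            "beta31": "-4.2E-03",
            "beta32": "4.3E-03",
        },
    }.items()
}

# per-stratum linear+log fits, printed at 2 significant figures
_TABLE2_ROWS: list[tuple[int, int, str, str, str, str, str, str, str]] = [
    (0, 1, "-2.0E-05", "2.9E-06", "-5.0E-05", "-9.3E-07", "4.0E-05", "1.3E-03", "-8.4E-06"),
    (0, 2, "-8.1E-05", "1.4E-06", "-2.1E-05", "-9.3E-07", "4.6E-05", "-2.1E-04", "7.6E-08"),
    (0, 3, "-1.2E-05", "5.9E-07", "-1.2E-05", "-2.6E-07", "1.1E-05", "2.6E-04", "-2.2E-06"),
    (0, 4, "-1.1E-04", "2.7E-07", "-1.7E-06", "-8.2E-07", "4.4E-05", "-1.8E-04", "2.9E-06"),
    (0, 5, "1.1E-04", "-3.6E-08", "3.9E-06", "4.9E-07", "-3.4E-05", "1.5E-04", "-8.2E-07"),
    (0, 6, "7.3E-05", "1.5E-07", "-4.0E-06", "4.8E-07", "-1.7E-05", "2.6E-04", "1.5E-06"),
    (0, 7, "2.5E-04", "8.6E-07", "-1.2E-05", "1.2E-06", "-8.2E-05", "8.2E-04", "-1.2E-05"),
    (0, 8, "4.8E-04", "1.4E-06", "-2.7E-05", "1.3E-06", "-6.9E-05", "-1.2E-03", "3.3E-05"),
    (0, 9, "6.6E-04", "3.6E-06", "-8.9E-05", "1.8E-06", "-5.7E-05", "-3.5E-03", "5.1E-05"),
    (1, 1, "1.3E-04", "9.1E-07", "-1.6E-05", "1.2E-06", "-6.5E-05", "2.3E-03", "-2.5E-05"),
    (1, 2, "-1.7E-04", "3.6E-07", "4.1E-06", "-8.0E-07", "4.8E-05", "4.3E-04", "-3.6E-06"),
    (1, 3, "-1.5E-05", "6.4E-07", "-7.0E-06", "-2.5E-07", "1.1E-05", "7.94E-05", "-2.5E-06"),
    (1, 4, "-1.5E-05", "1.0E-06", "-1.9E-05", "-5.5E-07", "2.2E-05", "1.4E-04", "-3.3E-06"),
    (1, 5, "8.6E-05", "8.6E-08", "3.7E-06", "4.8E-07", "-3.4E-05", "3.4E-04", "-5.6E-06"),
    (1, 6, "9.9E-05", "3.3E-07", "2.0E-06", "3.4E-07", "-3.6E-05", "4.7E-04", "-9.4E-06"),
    (1, 7, "5.3E-04", "1.5E-06", "-2.9E-05", "2.0E-06", "-1.4E-04", "2.5E-04", "-1.2E-06"),
    (1, 8, "8.2E-04", "1.9E-06", "-2.3E-05", "3.4E-06", "-2.3E-04", "-4.5E-04", "-2.0E-06"),
    (1, 9, "8.4E-04", "4.8E-06", "-1.3E-04", "2.0E-06", "-9.6E-05", "-1.6E-03", "4.6E-05"),
]

#: map (sex, age_group) -> coefficient dict of the linear+log family
TABLE2: dict[tuple[int, int], dict[str, float]] = {
    (sex, age): dict(zip(COEF_NAMES, map(float, coefs)))
    for sex, age, *coefs in _TABLE2_ROWS
}

#: same cells, kept as printed strings for digit-level comparison
TABLE2_PRINTED: dict[tuple[int, int], dict[str, str]] = {
    (sex, age): dict(zip(COEF_NAMES, coefs)) for sex, age, *coefs in _TABLE2_ROWS
}

# second-level g-functions; term keys follow the printed equations
_G_BLOCK_1_2: dict[str, dict[str, str]] = {
    "beta0": {"1": "3.340e-05", "sex": "4.042e-04", "age": "-5.738e-05", "sex_age": "-2.466e-04"},
    "beta11": {"1": "4.321e-06", "sex": "-2.865e-06", "age": "-1.463e-06", "sex_age": "9.143e-07"},
    "beta12": {"1": "-7.901e-05", "sex": "4.214e-05", "age": "2.891e-05", "sex_age": "-8.402e-06"},
    "beta21": {"1": "-9.365e-07", "sex": "4.096e-06", "age": "3.474e-09", "sex_age": "-1.984e-06"},
    "beta22": {"1": "3.37e-05", "sex": "-2.128e-04", "age": "5.929e-06", "sex_age": "1.078e-04"},
    "beta31": {"1": "2.826e-03", "sex": "1.282e-03", "age": "-1.519e-03", "sex_age": "-3.189e-04"},
    "beta32": {"1": "-1.693e-05", "sex": "-3.024e-05", "age": "8.502e-06", "sex_age": "1.331e-05"},
}

_G_BLOCK_3_7: dict[str, dict[str, str]] = {
    "beta0": {
        "1": "-1.118e-06",
        "sex": "-4.366e-06",
        "age": "-1.43e-05",
        "ln_age": "1.658e-05",
        "exp_age": "3.153e-07",
        "sex_age": "1.303e-05",
        "sex_ln_age": "-2.749e-05",
        "sex_exp_age": "1.67e-07",
    },
    "beta11": {"1": "1.867e-07", "sex": "2.569e-07", "exp_age": "5.21e-10", "sex_exp_age": "2.57e-10"},
    "beta12": {"1": "-2.652e-06", "sex": "-1.15e-06", "exp_age": "-6.831e-09", "sex_exp_age": "-1.041e-08"},
    "beta21": {"1": "-2.73e-07", "sex": "-2.182e-08", "exp_age": "1.419e-09", "sex_exp_age": "6.259e-10"},
    "beta22": {"1": "1.572e-05", "sex": "-4.796e-06", "exp_age": "-9.083e-08", "sex_exp_age": "-4.214e-08"},
    "beta31": {"1": "-4.051e-08", "sex": "3.256e-04", "age": "1.339e-04", "sex_age": "-6.687e-05"},
    "beta32": {"1": "8.94e-06", "sex": "-9.927e-06", "age": "-2.22e-06", "sex_age": "1.538e-06"},
}

#: multi-level models: block id -> (age set, g-function coefficient maps)
MULTILEVEL: dict[str, tuple[frozenset[int], dict[str, dict[str, float]]]] = {
    "mlm-ages-1-2": (
        frozenset({1, 2}),
        {name: {t: float(v) for t, v in terms.items()} for name, terms in _G_BLOCK_1_2.items()},
    ),
    "mlm-ages-3-7": (
        frozenset({3, 4, 5, 6, 7}),
        {name: {t: float(v) for t, v in terms.items()} for name, terms in _G_BLOCK_3_7.items()},
    ),
}

#: age groups excluded from the multi-level models
EXCLUDED_AGES = frozenset({8, 9})


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures, half-even on the mantissa.

    Matches the print format of the coefficient tables (e.g. 1.395e-06 ->
    1.4e-06, -2.398e-05 -> -2.4e-05).
    """
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    shift = d.adjusted() - (sig - 1)
    q = d.scaleb(-shift).quantize(Decimal(1), rounding=ROUND_HALF_EVEN).scaleb(shift)
    return float(q)


def _g_terms(sex: float, age: float) -> dict[str, float]:
    return {
        "1": 1.0,
        "sex": sex,
        "age": age,
        "ln_age": math.log(age),
        "exp_age": math.exp(age),
        "sex_age": sex * age,
        "sex_ln_age": sex * math.log(age),
        "sex_exp_age": sex * math.exp(age),
    }


def evaluate_published_g(model_id: str, coef_name: str, sex: int, age: int) -> float:
    """Evaluate one printed second-level g-function at (sex, age)."""
    ages, gset = MULTILEVEL[model_id]
    if age not in ages:
        raise ValueError(
            f"age group {age} outside the domain {sorted(ages)} of {model_id}"
        )
    terms = _g_terms(sex, age)
    return sum(c * terms[t] for t, c in gset[coef_name].items())


def _linear_log_terms(x1: float, x2: float, x3: float) -> dict[str, float]:
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


def _linear_exp_terms(x1: float, x2: float, x3: float) -> dict[str, float]:
    return {
        "beta0": 1.0,
        "beta11": x1,
        "beta12": math.exp(x1),
        "beta21": x2,
        "beta22": math.exp(x2),
        "beta31": x3,
        "beta32": math.exp(x3),
    }


def predict_published(
    model_id: str,
    x1: float,
    x2: float,
    x3: float,
    sex: int | None = None,
    age: int | None = None,
) -> float:
    """Predict a weekly outpatient rate from a published coefficient set.

    Parameters
    ----------
    model_id
        ``table1-M1``/``table1-M2``/``table1-M3`` (pooled), ``table2``
        (per-stratum; requires sex and age), or ``mlm-ages-1-2``/
        ``mlm-ages-3-7`` (multi-level; requires sex and age).
    x1, x2, x3
        Transformed predictors: temperature + 20 (°C), relative humidity
        (%), O₃ (ppm).
    """
    if model_id in TABLE1:
        coefs = TABLE1[model_id]
        if model_id == "table1-M1":
            terms = {"beta0": 1.0, "beta11": x1, "beta21": x2, "beta31": x3}
        elif model_id == "table1-M2":
            terms = _linear_log_terms(x1, x2, x3)
        else:
            terms = _linear_exp_terms(x1, x2, x3)
        return sum(c * terms[name] for name, c in coefs.items())

    if sex is None or age is None:
        raise ValueError(f"model {model_id!r} requires sex and age")

    if model_id == "table2":
        try:
            coefs = TABLE2[(sex, age)]
        except KeyError:
            raise ValueError(f"no published stratum (sex={sex}, age={age})") from None
        terms = _linear_log_terms(x1, x2, x3)
        return sum(c * terms[name] for name, c in coefs.items())

    if model_id in MULTILEVEL:
        if age in EXCLUDED_AGES:
            raise ValueError(
                f"age groups 8 and 9 were excluded from the multi-level models; got {age}"
            )
        terms = _linear_log_terms(x1, x2, x3)
        return sum(
            evaluate_published_g(model_id, name, sex, age) * terms[name]
            for name in COEF_NAMES
        )

    raise ValueError(f"unknown model id {model_id!r}")


def predict_multilevel_published(sex: int, age: int, x1: float, x2: float, x3: float) -> float:
    """Route a multi-level prediction to the age block covering ``age``."""
    if age in EXCLUDED_AGES:
        raise ValueError(
            f"age groups 8 and 9 were excluded from the multi-level models; got {age}"
        )
    for model_id, (ages, _) in MULTILEVEL.items():
        if age in ages:
            return predict_published(model_id, x1, x2, x3, sex=sex, age=age)
    raise ValueError(f"age group {age} not covered by any multi-level block")


def reconstruct_table2(sig: int = 2) -> pd.DataFrame:
    """Rebuild the ages-1-2 stratum coefficients from the printed g-functions.

    Evaluates the published ages-1-2 second-level equations at the four
    (sex, age) strata, rounds to ``sig`` significant figures, and compares
    with the printed per-stratum table. Because the four-point block was
    fitted with four-parameter forms (a saturated fit), cells should round
    back to their printed values. Three cells do not: β₀ at (sex=0,
    age=1) prints −2.0E−05 where the printed g₀ implies −2.4E−05 (a
    genuine inconsistency between the two published tables), and the two
    β₃₂ cells at age 2 sit so close to zero that the four-significant-
    figure precision of the printed g₃₂ coefficients cannot resolve them
    (reconstruction errors of a few 1e−9 flip the second digit). The
    remaining 25 of 28 cells match exactly at print precision.

    Returns a tidy frame with one row per (sex, age, coefficient) cell.
    """
    rows = []
    ages, _ = MULTILEVEL["mlm-ages-1-2"]
    for sex in (0, 1):
        for age in sorted(ages):
            for name in COEF_NAMES:
                exact = evaluate_published_g("mlm-ages-1-2", name, sex, age)
                rounded = round_sigfigs(exact, sig)
                printed = float(TABLE2_PRINTED[(sex, age)][name])
                rows.append(
                    {
                        "sex": sex,
                        "age_group": age,
                        "coefficient": name,
                        "reconstructed": exact,
                        "reconstructed_rounded": rounded,
                        "printed": printed,
                        "match": rounded == printed,
                    }
                )
    return pd.DataFrame(rows)


def o3_response_curve(
    model_id: str,
    o3_grid: list[float],
    temp_rh_combos: list[tuple[float, float]] | None = None,
    sex: int | None = None,
    age: int | None = None,
) -> pd.DataFrame:
    """Predicted rate over an O₃ grid for fixed (temperature, humidity) combos.

    Default combos bracket the study-period averages of 12.34 °C and
    58.5 %: a low (2 °C, 45 %), average (12.34 °C, 58.5 %) and high
    (24.7 °C, 70.7 %) condition, the latter matching the summer-quarter
    averages.
    """
    if temp_rh_combos is None:
        temp_rh_combos = [(2.0, 45.0), (12.34, 58.5), (24.7, 70.7)]
    rows = []
    for temp_c, rh in temp_rh_combos:
        for o3 in o3_grid:
            if o3 <= 0:
                raise ValueError(f"O₃ grid values must be positive, got {o3}")
            rate = predict_published(model_id, temp_c + 20.0, rh, o3, sex=sex, age=age)
            rows.append(
                {"temp_c": temp_c, "rh_pct": rh, "o3_ppm": o3, "predicted_rate": rate}
            )
    return pd.DataFrame(rows)
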