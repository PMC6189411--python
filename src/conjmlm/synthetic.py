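"""Synthetic weekly environment and outpatient-count generation.

The study's registry and monitoring data are not publicly deposited, so
every pipeline stage is exercised on synthetic data that emulates the
study conditions: 156 weeks of Seoul-like seasonal meteorology and ozone
(annual sinusoids plus Gaussian noise) and sex × age-group outpatient
counts whose expected rates follow a specified truth model — by default
the published per-stratum coefficients — with Poisson or
rounded-Gaussian count noise.

Defaults: temperature mean 12.34 °C with ±12.5 °C seasonal swing and
relative humidity mean 58.5 % (the study-period averages; the swing
brackets the printed quarterly extremes of −0.8 and 24.7 °C); ozone mean
0.018 ppm with ±0.012 ppm swing, i.e. a 0.005–0.04 ppm regime around the
156-week average. Stratum populations default to 5·10⁵ so weekly
expected counts land in the observed range of a few hundred.

One integer seed drives two independently derived substreams (environment
and counts), so changing the count noise never perturbs the environment
series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .level1 import family_terms
from .level2 import CoefficientTable, MultiLevelModel

#: floor for the expected rate before count generation; fitted linear
#: models can predict negative rates at extreme inputs and a count mean
#: must stay positive
RATE_FLOOR = 1e-8

ALL_STRATA = [(s, a) for s in (0, 1) for a in range(1, 10)]


def _default_populations() -> dict[tuple[int, int], int]:
    return {stratum: 500_000 for stratum in ALL_STRATA}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study conditions."""

    n_weeks: int = 156
    seed: int = 0
    temp_mean: float = 12.34  # °C
    temp_amplitude: float = 12.5
    rh_mean: float = 58.5  # %
    rh_amplitude: float = 9.75
    o3_mean: float = 0.018  # ppm
    o3_amplitude: float = 0.012
    temp_noise_sd: float = 1.5
    rh_noise_sd: float = 4.0
    o3_noise_sd: float = 0.0015
    phase: float = -math.pi / 2  # week 0 at the seasonal minimum (January)
    period_weeks: float = 52.0
    rate_noise: float = 0.05  # relative dispersion of counts beyond Poisson
    count_model: str = "poisson"  # or "rounded-gaussian"
    populations: dict[tuple[int, int], int] = field(default_factory=_default_populations)

    def validate(self) -> None:
        if self.n_weeks < 6:
            raise ValueError(f"n_weeks must be >= 6, got {self.n_weeks}")
        if not (0 <= self.rh_amplitude < self.rh_mean):
            raise ValueError("rh_amplitude must be non-negative and below rh_mean")
        if not (0 <= self.o3_amplitude < self.o3_mean):
            raise ValueError("o3_amplitude must be non-negative and below o3_mean")
        if self.o3_mean - self.o3_amplitude - 3 * self.o3_noise_sd <= 0:
            raise ValueError(
                "o3_mean - o3_amplitude - 3*o3_noise_sd must stay positive "
                "(log-transform safety)"
            )
        for sd in (self.temp_noise_sd, self.rh_noise_sd, self.o3_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be non-negative")
        if self.rate_noise < 0:
            raise ValueError(f"rate_noise must be non-negative, got {self.rate_noise}")
        if self.count_model not in ("poisson", "rounded-gaussian"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if not self.populations:
            raise ValueError("populations must not be empty")
        for stratum, pop in self.populations.items():
            if pop <= 0:
                raise ValueError(f"population for stratum {stratum} must be positive")


@dataclass
class TruthModel:
    """The model generating expected rates: a stratum table or a composite."""

    table: CoefficientTable | None = None
    multilevel: MultiLevelModel | None = None

    def __post_init__(self) -> None:
        if (self.table is None) == (self.multilevel is None):
            raise ValueError("specify exactly one of table or multilevel")

    @property
    def kind(self) -> str:
        return "table" if self.table is not None else "multilevel"

    def covers(self, stratum: tuple[int, int]) -> bool:
        if self.table is not None:
            return stratum in self.table.coefficients
        sex, age = stratum
        return age not in self.multilevel.excluded_ages

    def expected_rate(self, sex: int, age: int, x1: float, x2: float, x3: float) -> float:
        if self.table is not None:
            c = self.table.coefficients[(sex, age)]
            terms = family_terms(self.table.family_id, x1, x2, x3)
            return sum(c[name] * value for name, value in terms.items())
        return self.multilevel.predict(sex, age, x1, x2, x3)

    @classmethod
    def published_table2(cls) -> "TruthModel":
        """Published per-stratum coefficients; covers all 18 strata."""
        return cls(table=CoefficientTable.from_published_table2())

    @classmethod
    def published_multilevel(cls) -> "TruthModel":
        """Published composite model; ages 8 and 9 are out of domain."""
        return cls(multilevel=MultiLevelModel.from_published())


def _substreams(config: SyntheticConfig) -> tuple[np.random.Generator, np.random.Generator]:
    env_ss, count_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(env_ss), np.random.default_rng(count_ss)


def generate_weekly_environment(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate the weekly temperature / humidity / ozone series.

    Each variable is mean + amplitude·sin(2π·week/period + phase) plus
    independent Gaussian noise; humidity is clamped to (0, 100] and ozone
    to a small positive floor. Deterministic given the config seed.
    """
    config.validate()
    rng, _ = _substreams(config)
    week = np.arange(config.n_weeks)
    season = np.sin(2 * np.pi * week / config.period_weeks + config.phase)
    temp = config.temp_mean + config.temp_amplitude * season
    rh = config.rh_mean + config.rh_amplitude * season
    o3 = config.o3_mean + config.o3_amplitude * season
    if config.temp_noise_sd:
        temp = temp + rng.normal(0, config.temp_noise_sd, config.n_weeks)
    if config.rh_noise_sd:
        rh = rh + rng.normal(0, config.rh_noise_sd, config.n_weeks)
    if config.o3_noise_sd:
        o3 = o3 + rng.normal(0, config.o3_noise_sd, config.n_weeks)
    rh = np.clip(rh, 1e-6, 100.0)
    o3 = np.maximum(o3, 1e-6)
    return pd.DataFrame({"week": week, "temp_c": temp, "rh_pct": rh, "o3_ppm": o3})


def generate_outpatient_observations(
    env: pd.DataFrame, truth: TruthModel, config: SyntheticConfig
) -> pd.DataFrame:
    """Draw weekly counts per stratum around the truth model's expected rate.

    For each week × stratum the expected rate μ is the truth-model
    prediction floored at a small positive value; the count mean is
    μ·population. ``poisson`` draws Poisson counts (with an extra
    mean-one gamma multiplier when rate_noise > 0, i.e. negative-binomial
    style overdispersion); ``rounded-gaussian`` rounds
    mean·(1 + rate_noise·z) to the nearest non-negative integer, so
    rate_noise = 0 yields exactly round(mean). Deterministic given the
    config seed.
    """
    config.validate()
    if env.empty:
        raise ValueError("empty environment series")
    _, rng = _substreams(config)
    strata = sorted(config.populations)
    for stratum in strata:
        if not truth.covers(stratum):
            raise ValueError(f"truth model does not cover stratum {stratum}")
    x1 = env["temp_c"].to_numpy() + 20.0
    x2 = env["rh_pct"].to_numpy()
    x3 = env["o3_ppm"].to_numpy()
    weeks = env["week"].to_numpy()
    rows = []
    for sex, age in strata:
        pop = config.populations[(sex, age)]
        mu = np.array(
            [
                max(truth.expected_rate(sex, age, a, b, c), RATE_FLOOR)
                for a, b, c in zip(x1, x2, x3)
            ]
        )
        mean_counts = mu * pop
        if config.count_model == "poisson":
            if config.rate_noise > 0:
                shape = 1.0 / config.rate_noise**2
                mean_counts = mean_counts * rng.gamma(shape, 1.0 / shape, len(mu))
            counts = rng.poisson(mean_counts)
        else:
            z = rng.standard_normal(len(mu)) if config.rate_noise > 0 else 0.0
            counts = np.maximum(
                np.rint(mean_counts * (1.0 + config.rate_noise * z)), 0
            ).astype(np.int64)
        for w, n in zip(weeks, counts):
            rows.append(
                {
                    "week": int(w),
                    "sex": sex,
                    "age_group": age,
                    "count": int(n),
                    "population": pop,
                }
            )
    obs = pd.DataFrame(rows)
    obs["rate"] = obs["count"] / obs["population"]
    return obs.sort_values(["week", "sex", "age_group"], ignore_index=True)


def simulate_dataset(
    config: SyntheticConfig, truth: TruthModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Environment and observation frames for one synthetic study."""
    if truth is None:
        truth = TruthModel.published_table2()
    env = generate_weekly_environment(config)
    obs = generate_outpatient_observations(env, truth, config)
    return env, obs
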