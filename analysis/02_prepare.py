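#!/usr/bin/env python
"""Prepare the analysis dataset: predictor transforms (x1 = T + 20, x2 = RH,
x3 = O₃), positive-correlation screening of the candidate predictors against
the pooled weekly rate, and the one-test-week-per-three-weeks split."""

from pathlib import Path

import pandas as pd

from conjmlm import preprocessing
from conjmlm.evaluation import pooled_weekly_rates

SEED = 2026
OUT = Path("results")


def main() -> None:
    env = pd.read_csv(OUT / "environment.csv")
    obs = preprocessing.add_rates(pd.read_csv(OUT / "observations.csv"))

    env_t = preprocessing.transform_predictors(env)
    env_t.to_csv(OUT / "predictors.csv", index=False)

    pooled = pooled_weekly_rates(obs).merge(env_t, on="week")
    retained, screening = preprocessing.screen_predictors(
        pooled[["temp_c", "rh_pct", "o3_ppm"]], pooled["rate"]
    )
    screening.to_csv(OUT / "screening.csv", index=False)

    split = preprocessing.split_weeks(len(env), SEED)
    split.to_csv(OUT / "split.csv", index=False)

    print("predictor screening against the pooled weekly rate:")
    for _, row in screening.iterrows():
        print(f"  {row.candidate}: r = {row.pearson_r:+.3f} (r² = {row.r_squared:.3f})"
              f" -> {'retained' if row.retained else 'removed'}")
    n_test = (split["label"] == "test").sum()
    print(f"split: {n_test} test weeks, {len(split) - n_test} training weeks")


if __name__ == "__main__":
    main()
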