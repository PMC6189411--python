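#!/usr/bin/env python
"""Two-stage fit: level-1 models per (sex, age) stratum, second-level
g-functions over sex and age, and the composite models for the two age
blocks (ages 1–2 and 3–7; ages 8–9 excluded).

Reports the composite fit twice: under the registry-scale default
conditions (Poisson counts of ~10–100 per stratum-week), where the
independent smoothing of collinear stratum coefficients amplifies noise
and the wide block degrades badly, and under a low-noise validation
regime where the procedure's own smoothing is the only error source."""

import json
from pathlib import Path

import pandas as pd

from conjmlm import level2, preprocessing
from conjmlm.synthetic import SyntheticConfig, TruthModel, simulate_dataset

SEED = 2026
OUT = Path("results")


def fit_and_score(data, split):
    table = level2.fit_per_stratum("M2", data, split)
    mlm = level2.fit_multilevel(table)
    return table, mlm, level2.multilevel_stats(mlm, data, split)


def main() -> None:
    env_t = pd.read_csv(OUT / "predictors.csv")
    obs = preprocessing.add_rates(pd.read_csv(OUT / "observations.csv"))
    split = pd.read_csv(OUT / "split.csv")
    data = obs.merge(env_t[["week", "x1", "x2", "x3"]], on="week")

    table, mlm, stats = fit_and_score(data, split)
    table.to_frame().to_csv(OUT / "stratum_coefficients.csv", index=False)
    gdump = {
        block: {name: {"form": g.form_id, "r2": g.r2, "coefficients": g.coefficients}
                for name, g in gset.items()}
        for block, gset in mlm.blocks.items()
    }
    (OUT / "g_functions.json").write_text(json.dumps(gdump, indent=2))

    print("composite fit, default registry-scale conditions:")
    for block, st in stats.items():
        print(f"  {block}: R² = {st.r2:.3f}, out-of-sample R² = {st.r2_out:.3f}")
    print("  (the wide block degrades sharply once stratum fits are noisy: each")
    print("   coefficient is smoothed independently, which breaks the error")
    print("   cancellation between the collinear x and ln x terms)")

    # low-noise validation: truth is the published composite itself
    truth = TruthModel.published_multilevel()
    pops = {(s, a): 5_000_000 for s in (0, 1) for a in range(1, 8)}
    cfg = SyntheticConfig(seed=SEED, count_model="rounded-gaussian",
                          rate_noise=0.005, populations=pops)
    env_v, obs_v = simulate_dataset(cfg, truth)
    env_vt = preprocessing.transform_predictors(env_v)
    data_v = obs_v.merge(env_vt[["week", "x1", "x2", "x3"]], on="week")
    split_v = preprocessing.split_weeks(cfg.n_weeks, SEED)
    _, _, stats_v = fit_and_score(data_v, split_v)

    rows = []
    print("composite fit, low-noise validation (truth = published composite):")
    for block, st in stats_v.items():
        print(f"  {block}: R² = {st.r2:.3f}, adj R² = {st.adj_r2:.3f}, "
              f"out-of-sample R² = {st.r2_out:.3f}")
        rows.append({"block": block, "r2": st.r2, "adj_r2": st.adj_r2,
                     "p_value": st.p_value, "r2_out": st.r2_out,
                     "n_train": st.n_train, "n_test": st.n_test})
    pd.DataFrame(rows).to_csv(OUT / "multilevel_validation.csv", index=False)


if __name__ == "__main__":
    main()
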