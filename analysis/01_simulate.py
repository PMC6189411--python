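#!/usr/bin/env python
"""Generate the synthetic 3-year study: 156 weeks of Seoul-like weather,
ozone, and sex/age-stratified conjunctivitis outpatient counts whose
expected rates follow the published per-stratum models."""

from pathlib import Path

from conjmlm import preprocessing
from conjmlm.synthetic import SyntheticConfig, simulate_dataset

SEED = 2026
OUT = Path("results")


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    env, obs = simulate_dataset(cfg)
    OUT.mkdir(exist_ok=True)
    env.to_csv(OUT / "environment.csv", index=False)
    obs[preprocessing.OBS_COLUMNS].to_csv(OUT / "observations.csv", index=False)

    quarter = env.assign(q=env["week"] % 52 // 13).groupby("q").mean()
    weekly_counts = obs.groupby("week")["count"].sum()
    print(f"simulated {cfg.n_weeks} weeks × {len(cfg.populations)} strata (seed {SEED})")
    print(f"temperature mean {env['temp_c'].mean():.2f} °C, "
          f"range {env['temp_c'].min():.1f} to {env['temp_c'].max():.1f}")
    print(f"O₃ mean {env['o3_ppm'].mean():.4f} ppm, "
          f"range {env['o3_ppm'].min():.4f} to {env['o3_ppm'].max():.4f}")
    print("quarterly temperature means:", [f"{v:.1f}" for v in quarter["temp_c"]])
    print(f"weekly outpatients (all strata): mean {weekly_counts.mean():.0f}, "
          f"range {weekly_counts.min()} to {weekly_counts.max()}")


if __name__ == "__main__":
    main()
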