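"""Per-stratum fits, g-function selection, and the composite two-stage model."""

import math

import numpy as np
import pytest

from conjmlm import level2, preprocessing
from conjmlm.level1 import ALL_COEF_NAMES
from conjmlm.level2 import (
    BLOCKS,
    CoefficientTable,
    GFunction,
    MultiLevelModel,
    evaluate_g,
    fit_g,
    fit_multilevel,
    fit_per_stratum,
    multilevel_stats,
)
from conjmlm.published import MULTILEVEL
from conjmlm.synthetic import SyntheticConfig, TruthModel, simulate_dataset


def _table_from(values: dict) -> CoefficientTable:
    coefs = {
        stratum: {**{n: 0.0 for n in ALL_COEF_NAMES}, **vals}
        for stratum, vals in values.items()
    }
    return CoefficientTable(family_id="M2", coefficients=coefs)


class TestFitPerStratum:
    def test_all_18_strata_fitted(self, small_dataset):
        data, split = small_dataset
        table = fit_per_stratum("M2", data, split)
        assert len(table.strata) == 18
        frame = table.to_frame()
        assert set(frame.columns) == {"sex", "age_group", *ALL_COEF_NAMES}

    def test_single_stratum(self, small_dataset):
        data, split = small_dataset
        one = data[(data.sex == 0) & (data.age_group == 3)]
        table = fit_per_stratum("M2", one, split)
        assert table.strata == [(0, 3)]

    def test_contrasting_strata_recover_their_own_truth(self):
        # two strata generated from very different coefficient vectors
        truth = _table_from(
            {
                (0, 1): {"beta0": 1e-4, "beta11": 5e-6},
                (1, 1): {"beta0": 5e-4, "beta11": -5e-6},
            }
        )
        cfg = SyntheticConfig(
            seed=3,
            n_weeks=52,
            count_model="rounded-gaussian",
            rate_noise=0.0,
            populations={(0, 1): 10**8, (1, 1): 10**8},
        )
        env, obs = simulate_dataset(cfg, TruthModel(table=truth))
        env_t = preprocessing.transform_predictors(env)
        data = obs.merge(env_t[["week", "x1", "x2", "x3"]], on="week")
        split = preprocessing.split_weeks(52, 3)
        table = fit_per_stratum("M2", data, split)
        for stratum in ((0, 1), (1, 1)):
            est = table.coefficients[stratum]
            want = truth.coefficients[stratum]
            assert est["beta0"] == pytest.approx(want["beta0"], rel=1e-3)
            assert est["beta11"] == pytest.approx(want["beta11"], rel=1e-3)


class TestFitG:
    def test_saturated_block_interpolates_exactly(self, rng):
        betas = {(s, a): {"beta11": float(rng.normal())} for s in (0, 1) for a in (1, 2)}
        table = _table_from(betas)
        g = fit_g(table, "beta11", (1, 2), candidates=("linear",))
        for (s, a), vals in betas.items():
            assert evaluate_g(g, s, a) == pytest.approx(vals["beta11"], rel=1e-9)
        assert g.r2 == 1.0

    def test_constant_beta_gives_flat_g(self):
        table = _table_from({(s, a): {"beta21": 7e-6} for s in (0, 1) for a in (3, 4, 5, 6, 7)})
        g = fit_g(table, "beta21", BLOCKS["ages-3-7"])
        assert g.r2 == pytest.approx(1.0)
        for s in (0, 1):
            for a in (3, 5, 7):
                assert evaluate_g(g, s, a) == pytest.approx(7e-6, rel=1e-9)

    def test_exp_truth_selected_and_recovered_over_wide_block(self):
        c = {"1": 2e-6, "sex": -1e-6, "exp_age": 3e-9, "sex_exp_age": 1e-9}
        betas = {
            (s, a): {
                "beta12": c["1"] + c["sex"] * s + c["exp_age"] * math.exp(a)
                + c["sex_exp_age"] * s * math.exp(a)
            }
            for s in (0, 1)
            for a in (3, 4, 5, 6, 7)
        }
        g = fit_g(_table_from(betas), "beta12", BLOCKS["ages-3-7"])
        assert g.form_id == "exp"
        assert g.r2 == pytest.approx(1.0)
        for term, value in c.items():
            assert g.coefficients[term] == pytest.approx(value, rel=1e-6)

    def test_saturated_tie_prefers_linear_form(self, rng):
        # 4 points, 4 parameters: every candidate interpolates; linear wins
        betas = {(s, a): {"beta31": float(rng.normal())} for s in (0, 1) for a in (1, 2)}
        g = fit_g(_table_from(betas), "beta31", (1, 2))
        assert g.form_id == "linear"

    def test_intercept_uses_full_form_on_wide_block(self, rng):
        betas = {(s, a): {"beta0": float(rng.normal())} for s in (0, 1) for a in (3, 4, 5, 6, 7)}
        g = fit_g(_table_from(betas), "beta0", BLOCKS["ages-3-7"])
        assert g.form_id == "g0-full"
        assert len(g.coefficients) == 8

    def test_more_parameters_than_strata_rejected(self, rng):
        betas = {(s, a): {"beta0": 1.0} for s in (0, 1) for a in (1, 2)}
        with pytest.raises(ValueError, match="parameters"):
            fit_g(_table_from(betas), "beta0", (1, 2), candidates=("g0-full",))


class TestPublishedRoundTrip:
    def test_refit_to_published_g_recovers_published_coefficients(self):
        """β values generated by the printed ages-1-2 g's refit to the same g's."""
        _, gset = MULTILEVEL["mlm-ages-1-2"]
        table = _table_from(
            {
                (s, a): {
                    name: sum(
                        c * {"1": 1.0, "sex": s, "age": a, "sex_age": s * a}[t]
                        for t, c in gset[name].items()
                    )
                    for name in ALL_COEF_NAMES
                }
                for s in (0, 1)
                for a in (1, 2)
            }
        )
        for name in ALL_COEF_NAMES:
            g = fit_g(table, name, (1, 2))
            for term, value in gset[name].items():
                assert g.coefficients[term] == pytest.approx(value, rel=1e-6), (name, term)


class TestMultiLevelModel:
    def test_block1_composite_equals_stratum_fit(self, small_dataset):
        data, split = small_dataset
        table = fit_per_stratum("M2", data, split)
        mlm = fit_multilevel(table)
        # saturated block: g interpolates, so composite == stratum-specific prediction
        row = data[(data.sex == 1) & (data.age_group == 2)].iloc[0]
        stratum_pred = float(
            np.dot(
                list(table.coefficients[(1, 2)].values()),
                [1, row.x1, math.log(row.x1), row.x2, math.log(row.x2), row.x3, math.log(row.x3)],
            )
        )
        assert mlm.predict(1, 2, row.x1, row.x2, row.x3) == pytest.approx(stratum_pred, rel=1e-9)

    def test_block2_prediction_hand_evaluated(self):
        mlm = MultiLevelModel.from_published()
        x1, x2, x3 = 32.34, 58.5, 0.018
        c = mlm.coefficients_at(0, 5)
        by_hand = (
            c["beta0"]
            + c["beta11"] * x1
            + c["beta12"] * math.log(x1)
            + c["beta21"] * x2
            + c["beta22"] * math.log(x2)
            + c["beta31"] * x3
            + c["beta32"] * math.log(x3)
        )
        assert mlm.predict(0, 5, x1, x2, x3) == pytest.approx(by_hand, rel=1e-12)

    def test_excluded_ages_raise(self):
        mlm = MultiLevelModel.from_published()
        for age in (8, 9):
            with pytest.raises(ValueError, match="excluded"):
                mlm.predict(0, age, 32.34, 58.5, 0.018)

    def test_assemble_rejects_incomplete_blocks(self):
        g = GFunction("beta0", "linear", {"1": 0.0}, (1, 2), 1.0)
        with pytest.raises(ValueError, match="missing"):
            level2.assemble_multilevel({"ages-1-2": {"beta0": g}})


class TestMultilevelStats:
    def test_perfect_model_scores_one_in_both_blocks(self):
        truth = TruthModel.published_multilevel()
        pops = {(s, a): 10**9 for s in (0, 1) for a in range(1, 8)}
        cfg = SyntheticConfig(
            seed=9, n_weeks=52, count_model="rounded-gaussian", rate_noise=0.0,
            populations=pops,
        )
        env, obs = simulate_dataset(cfg, truth)
        env_t = preprocessing.transform_predictors(env)
        data = obs.merge(env_t[["week", "x1", "x2", "x3"]], on="week")
        split = preprocessing.split_weeks(52, 9)
        stats = multilevel_stats(truth.multilevel, data, split)
        for block in BLOCKS:
            assert stats[block].r2 == pytest.approx(1.0, abs=1e-6)
            assert stats[block].r2_out == pytest.approx(1.0, abs=1e-6)

    def test_out_of_sample_r2_matches_direct_formula(self, small_dataset):
        data, split = small_dataset
        table = fit_per_stratum("M2", data, split)
        mlm = fit_multilevel(table)
        stats = multilevel_stats(mlm, data, split)
        _, test_w = preprocessing.train_test_weeks(split)
        rows = data[data["week"].isin(test_w) & data["age_group"].isin(BLOCKS["ages-1-2"])]
        y = rows["rate"].to_numpy()
        yhat = mlm.predict_frame(rows)
        expected = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert stats["ages-1-2"].r2_out == pytest.approx(expected, abs=1e-12)

    def test_block_r2_improves_as_noise_shrinks(self):
        """Composite fit quality under a multi-level truth, noisy vs quiet counts.

        The two-stage procedure smooths each coefficient independently,
        which amplifies stratum-fit noise in the wide age block; the
        pooled R² must recover toward 1 as count noise shrinks.
        """
        truth = TruthModel.published_multilevel()
        pops = {(s, a): 5_000_000 for s in (0, 1) for a in range(1, 8)}
        r2 = {}
        for noise in (0.02, 0.002):
            cfg = SyntheticConfig(
                seed=3, count_model="rounded-gaussian", rate_noise=noise, populations=pops
            )
            env, obs = simulate_dataset(cfg, truth)
            env_t = preprocessing.transform_predictors(env)
            data = obs.merge(env_t[["week", "x1", "x2", "x3"]], on="week")
            split = preprocessing.split_weeks(cfg.n_weeks, 3)
            table = fit_per_stratum("M2", data, split)
            stats = multilevel_stats(fit_multilevel(table), data, split)
            r2[noise] = {b: s.r2 for b, s in stats.items()}
        for block in BLOCKS:
            assert r2[0.002][block] > r2[0.02][block]
        assert 0.5 <= r2[0.002]["ages-3-7"] < 1.0
        assert 0.5 <= r2[0.002]["ages-1-2"] < 1.0
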