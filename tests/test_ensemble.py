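"""Perturbation settings, pruning arithmetic, PLS stacking and the full
pipeline's bookkeeping and determinism."""

import numpy as np
import pytest

from semisoft.config import ModelHyper, PLOSettings, RunConfig
from semisoft.datasets import SyntheticConfig, make_ssl_split, simulate_batches
from semisoft.elm import fit_nclelm, init_nclelm, predict_nclelm
from semisoft.ensemble import (
    Scaler,
    StackedEnsemble,
    average_ensemble,
    build_ssnclelm,
    fit_stacking,
    generate_settings,
    performance_improvement_ratio,
    predict_ensemble,
    prune_by_pir,
    run_full_pipeline,
)
from semisoft.metrics import rmse
from semisoft.pseudolabel import GAConfig


def tiny_config(seed=0):
    return RunConfig(
        model=ModelHyper(n_elm=3, n_node=8, lam=0.6),
        plo=PLOSettings(
            m=2, u_prime=12,
            gamma1_grid=(0.0, 0.1), gamma2_grid=(0.0,), gamma3_grid=(0.1,),
        ),
        ga=GAConfig(npop=10, ngen=5),
        seed=seed,
    )


@pytest.fixture(scope="module")
def tiny_data():
    table = simulate_batches(
        SyntheticConfig(n_batches=6, samples_per_batch=15, n_inputs=5,
                        noise_sd=0.05, rng_seed=4)
    )
    return make_ssl_split(table, n_labeled=20, n_val=15, rng_seed=5)


class TestGenerateSettings:
    def test_full_paper_grid_yields_125_settings(self):
        grids = ((0, 0.01, 0.1, 0.5, 1),) * 3
        settings = generate_settings(grids, m=3, base_seed=0)
        assert len(settings) == 125
        assert sum(len(s.model_seeds) for s in settings) == 375

    def test_single_point_grid(self):
        settings = generate_settings(((0.5,), (0.5,), (0.5,)), m=1, base_seed=1)
        assert len(settings) == 1
        assert settings[0].gammas == (0.5, 0.5, 0.5)

    def test_cartesian_product_enumerated_once(self):
        settings = generate_settings(((0, 1), (0, 0.5, 1), (0.2,)), m=2, base_seed=2)
        assert len(settings) == 6
        assert len({s.gammas for s in settings}) == 6

    def test_deterministic_seeds(self):
        a = generate_settings(((0, 1),) * 3, m=2, base_seed=7)
        b = generate_settings(((0, 1),) * 3, m=2, base_seed=7)
        assert [s.model_seeds for s in a] == [s.model_seeds for s in b]
        assert [s.ga_seed for s in a] == [s.ga_seed for s in b]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_settings(((), (1,), (1,)), m=2, base_seed=0)


class TestBuildSsnclelm:
    def test_models_share_input_layers_with_counterparts(self, tiny_data):
        cfg = tiny_config()
        scaler = Scaler.fit(np.vstack([tiny_data.X_l, tiny_data.X_u]))
        setting = generate_settings(
            ((0.1,), (0.0,), (0.1,)), m=2, base_seed=3
        )[0]
        build = build_ssnclelm(
            setting, scaler.transform(tiny_data.X_l), tiny_data.y_l,
            scaler.transform(tiny_data.X_u), cfg.model,
            u_prime=12, ga_config=cfg.ga,
        )
        assert len(build.ss_models) == len(build.sup_models) == 2
        for ss, sup in zip(build.ss_models, build.sup_models):
            for a, b in zip(ss.members, sup.members):
                assert a.input_weights.tobytes() == b.input_weights.tobytes()
                assert a.biases.tobytes() == b.biases.tobytes()
        assert build.y_pl.shape == (12,)
        # pseudo labels respect the GPR-derived box, hence are finite
        assert np.isfinite(build.y_pl).all()

    def test_zero_u_prime_rejected(self, tiny_data):
        cfg = tiny_config()
        setting = generate_settings(((0.1,),) * 3, m=2, base_seed=3)[0]
        with pytest.raises(ValueError):
            build_ssnclelm(
                setting, tiny_data.X_l, tiny_data.y_l, tiny_data.X_u,
                cfg.model, u_prime=0, ga_config=cfg.ga,
            )


class TestPir:
    def test_equal_rmse_gives_zero_and_retained_at_zero_threshold(self):
        assert performance_improvement_ratio(0.5, 0.5) == 0.0

    def test_perfect_semi_supervised_model(self):
        assert performance_improvement_ratio(0.4, 0.0) == 1.0

    def test_degradation_is_negative(self):
        assert performance_improvement_ratio(1.0, 1.2) == pytest.approx(-0.2)

    def test_degenerate_zero_init(self):
        assert performance_improvement_ratio(0.0, 0.0) == 0.0
        assert performance_improvement_ratio(0.0, 0.1) == float("-inf")

    def test_prune_retains_by_threshold_and_falls_back(self, tiny_data, rng):
        # fabricate two builds whose models are real but tiny
        X = rng.normal(size=(20, 3))
        y = np.sin(X[:, 0])
        good = fit_nclelm(init_nclelm(3, 6, 2, 0.5, 1).members, X, y, 0.5)
        records_input = type("B", (), {})()
        from semisoft.ensemble import BuildResult, PerturbationSetting

        setting = PerturbationSetting(0, (0, 0, 0), (1, 2), 3, 4, 5)
        build = BuildResult(setting, [good], [good], X, y, np.arange(20), 0.0, np.zeros(1))
        recs = prune_by_pir([build], X, y, pir_threshold=0.0)
        assert len(recs) == 1 and recs[0].retained  # identical models: PIR = 0
        # threshold just above 0 triggers the single-best fallback
        recs2 = prune_by_pir([build], X, y, pir_threshold=0.5)
        assert recs2[0].retained  # fallback keeps the best model

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            prune_by_pir([], np.zeros((0, 2)), np.zeros(0))


class TestStacking:
    def test_single_exact_model_gives_identity_regression(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0])
        model = fit_nclelm(init_nclelm(2, 15, 3, 0.3, 2).members, X, y, 0.3)
        # validation labels exactly equal to the base model's predictions
        y_val = predict_nclelm(model, X)
        ens = fit_stacking([model], X, y_val)
        assert ens.intercept == pytest.approx(0.0, abs=1e-6)
        assert ens.coef[0] == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(ens.predict(X), y_val, atol=1e-6)

    def test_duplicate_models_collinear_columns_tolerated(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.sin(X[:, 0]) + 0.05 * rng.normal(size=25)
        model = fit_nclelm(init_nclelm(2, 10, 3, 0.3, 4).members, X, y, 0.3)
        dup = fit_stacking([model, model, model], X, y)
        single = fit_stacking([model], X, y)
        np.testing.assert_allclose(dup.predict(X), single.predict(X), atol=1e-6)

    def test_full_rank_full_components_matches_ols(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.sin(X[:, 0]) + 0.2 * X[:, 1] + 0.05 * rng.normal(size=40)
        models = [
            fit_nclelm(init_nclelm(3, 6, 2, 0.4, s).members, X, y, 0.4)
            for s in (1, 2, 3)
        ]
        Z = np.column_stack([predict_nclelm(m, X) for m in models])
        pls_full = fit_stacking(models, X, y, max_components=3)
        if pls_full.n_components == 3:
            Z1 = np.column_stack([np.ones(40), Z])
            beta = np.linalg.lstsq(Z1, y, rcond=None)[0]
            assert pls_full.intercept == pytest.approx(beta[0], abs=1e-6)
            np.testing.assert_allclose(pls_full.coef, beta[1:], atol=1e-6)

    def test_no_models_is_state_error(self, rng):
        with pytest.raises(RuntimeError):
            fit_stacking([], rng.normal(size=(5, 2)), rng.normal(size=5))


class TestPredictEnsemble:
    def test_constant_when_all_coefficients_zero(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        model = fit_nclelm(init_nclelm(2, 4, 2, 0.2, 1).members, X, y, 0.2)
        ens = StackedEnsemble(models=(model,), coef=np.zeros(1), intercept=3.3, n_components=1)
        np.testing.assert_allclose(predict_ensemble(ens, X), 3.3)

    def test_matches_manual_weighted_sum(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        models = [
            fit_nclelm(init_nclelm(2, 5, 2, 0.2, s).members, X, y, 0.2) for s in (1, 2)
        ]
        ens = StackedEnsemble(
            models=tuple(models), coef=np.array([0.3, 0.6]), intercept=0.2, n_components=2
        )
        Xq = rng.normal(size=(3, 2))
        manual = 0.2 + 0.3 * predict_nclelm(models[0], Xq) + 0.6 * predict_nclelm(models[1], Xq)
        np.testing.assert_allclose(ens.predict(Xq), manual, rtol=1e-12)

    def test_simple_average_variant(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        models = [
            fit_nclelm(init_nclelm(2, 5, 2, 0.2, s).members, X, y, 0.2) for s in (3, 4)
        ]
        avg = average_ensemble(models)
        expected = 0.5 * (predict_nclelm(models[0], X) + predict_nclelm(models[1], X))
        np.testing.assert_allclose(avg.predict(X), expected, rtol=1e-12)

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit_nclelm(init_nclelm(3, 4, 2, 0.2, 1).members, X, y, 0.2)
        ens = StackedEnsemble(models=(model,), coef=np.ones(1), intercept=0.0, n_components=1)
        with pytest.raises(ValueError):
            ens.predict(np.zeros((2, 5)))


class TestFullPipeline:
    def test_smoke_run_and_bookkeeping(self, tiny_data):
        result = run_full_pipeline(tiny_data, tiny_config(seed=1))
        assert result.n_settings == 2
        assert result.n_built == 4  # K=2 settings x M=2
        assert 1 <= result.n_retained <= result.n_built
        assert all(r.pir >= 0 for r in result.records if r.retained) or result.fallback_used
        preds = result.ensemble.predict(tiny_data.X_val)
        assert preds.shape == tiny_data.y_val.shape

    def test_identical_seeds_give_identical_predictions(self, tiny_data):
        r1 = run_full_pipeline(tiny_data, tiny_config(seed=3))
        r2 = run_full_pipeline(tiny_data, tiny_config(seed=3))
        np.testing.assert_array_equal(
            r1.ensemble.predict(tiny_data.X_val), r2.ensemble.predict(tiny_data.X_val)
        )

    def test_different_seeds_change_models(self, tiny_data):
        r1 = run_full_pipeline(tiny_data, tiny_config(seed=3))
        r2 = run_full_pipeline(tiny_data, tiny_config(seed=4))
        a = r1.ensemble.models[0].members[0].input_weights
        b = r2.ensemble.models[0].members[0].input_weights
        assert a.tobytes() != b.tobytes()
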