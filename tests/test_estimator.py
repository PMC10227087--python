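"""Two-stage regression, fold construction, agreement statistics, recovery."""

import numpy as np
import pandas as pd
import pytest

from bpclip import estimator, pipeline, synth
from bpclip.estimator import (
    BPRegressionModel,
    BPRegressionResults,
    FitError,
    accuracy_report,
    bland_altman,
    compute_reference_mbp,
    cross_validate,
    make_folds,
)


class TestReferenceMbp:
    @pytest.mark.parametrize(
        "sbp, dbp, expected", [(120, 80, 93.3333333), (90, 60, 70.0)]
    )
    def test_formula(self, sbp, dbp, expected):
        assert compute_reference_mbp(sbp, dbp) == pytest.approx(expected)

    def test_approaches_sbp_as_pulse_pressure_vanishes(self):
        assert compute_reference_mbp(100.0, 100.0 - 1e-9) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_rejects_inverted_pair(self):
        with pytest.raises(ValueError):
            compute_reference_mbp(80.0, 120.0)


def toy_cohort(n=24, seed=0, noise=0.0):
    """Features linearly tied to SBP so stage 1 is exactly realizable."""
    rng = np.random.default_rng(seed)
    sbp = rng.uniform(90, 160, n)
    dbp = sbp - rng.uniform(30, 50, n)
    X = rng.uniform(0, 1, (n, estimator.N_FEATURES))
    X[:, 0] = (sbp - 90) / 70.0  # feature 0 encodes SBP exactly
    X[:, 1] = (dbp - 40) / 120.0  # feature 1 encodes DBP exactly
    if noise:
        X += rng.normal(0, noise, X.shape)
    return BPRegressionModel(np.clip(X, 0, 1), sbp, dbp)


class TestStage1:
    def test_realizable_function_recovered_at_small_penalty(self):
        model = toy_cohort(n=30, seed=1)
        res = model.fit(alphas=[1e-6])
        pred = res.predict(model.features)
        assert np.abs(pred["sbp_hat"] - model.sbp_ref).max() < 0.5
        assert np.abs(pred["mbp_hat"] - model.mbp_ref).max() < 0.5

    def test_infinite_penalty_collapses_to_training_mean(self):
        model = toy_cohort(n=20, seed=2)
        res = model.fit(alphas=[1e6])
        assert np.all(res.sbp_coef == 0.0)
        pred = res.predict(model.features)
        assert np.allclose(pred["sbp_hat"], model.sbp_ref.mean())
        assert np.allclose(pred["mbp_hat"], model.mbp_ref.mean())

    def test_degenerate_features_rejected(self):
        X = np.full((10, estimator.N_FEATURES), 0.5)
        sbp = np.linspace(100, 150, 10)
        model = BPRegressionModel(X, sbp, sbp - 40)
        with pytest.raises(FitError):
            model.fit()

    def test_too_few_subjects_rejected(self):
        model = toy_cohort(n=3)
        with pytest.raises(FitError):
            model.fit()


class TestStage2:
    def test_identity_coefficients_under_perfect_stage1(self):
        """With exact stage-1 predictions, MBP = SBP/3 + 2 DBP/3 forces
        DBP = -0.5 SBP + 1.5 MBP with zero intercept."""
        model = toy_cohort(n=30, seed=3)
        res = model.fit(alphas=[1e-8])
        assert res.dbp_coef[0] == pytest.approx(-0.5, abs=0.01)
        assert res.dbp_coef[1] == pytest.approx(1.5, abs=0.01)
        assert res.dbp_intercept == pytest.approx(0.0, abs=1.5)

    def test_residuals_orthogonal_to_predictors(self):
        model = toy_cohort(n=30, seed=4, noise=0.05)
        res = model.fit()
        pred = res.predict(model.features)
        Z = np.column_stack([pred["sbp_hat"], pred["mbp_hat"]])
        resid = model.dbp_ref - pred["dbp_hat"].to_numpy()
        assert np.abs(Z.T @ resid).max() < 1e-6 * np.abs(Z).max() * len(resid)


class TestMakeFolds:
    def test_24_subjects_12_disjoint_folds(self):
        folds = make_folds(range(24), seed=0)
        assert len(folds) == 12
        flat = [s for f in folds for s in f]
        assert sorted(flat) == list(range(24))  # disjoint cover, each once

    def test_four_subjects_two_folds(self):
        assert len(make_folds([3, 1, 2, 0], seed=5)) == 2

    def test_odd_roster_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_folds(range(5))

    def test_depends_only_on_roster_and_seed(self):
        a = make_folds([5, 1, 9, 3], seed=7)
        b = make_folds([9, 3, 5, 1], seed=7)
        assert a == b


class TestAgreementStatistics:
    def test_bland_altman_bias_is_mean_error(self, rng):
        pred = rng.normal(120, 10, 50)
        ref = rng.normal(120, 10, 50)
        ba = bland_altman(pred, ref)
        assert ba["bias"] == pytest.approx(np.mean(pred - ref), abs=1e-12)
        assert ba["loa_high"] - ba["loa_low"] == pytest.approx(
            2 * 1.96 * np.std(pred - ref, ddof=1)
        )

    def test_report_mae_form(self):
        df = pd.DataFrame(
            {
                "sbp_hat": [120.0, 130.0],
                "sbp_ref": [118.0, 134.0],
                "mbp_hat": [90.0, 95.0],
                "mbp_ref": [90.0, 95.0],
                "dbp_hat": [80.0, 75.0],
                "dbp_ref": [82.0, 74.0],
            }
        )
        rep = accuracy_report(df)
        assert rep["sbp"]["mae"] == pytest.approx(3.0)
        assert rep["mbp"]["mae"] == 0.0
        assert rep["dbp"]["bias"] == pytest.approx(-0.5)


class TestCrossValidate:
    def test_identical_subjects_give_zero_error(self):
        n = 8
        X = np.tile(np.linspace(0, 1, estimator.N_FEATURES), (n, 1))
        X[:, 0] += np.arange(n) * 1e-6  # break exact degeneracy only
        model = BPRegressionModel(
            X, np.full(n, 120.0), np.full(n, 80.0)
        )
        res = cross_validate(model, seed=0)
        assert res.report["sbp"]["mae"] == pytest.approx(0.0, abs=1e-6)
        assert res.report["dbp"]["mae"] == pytest.approx(0.0, abs=1e-6)
        assert res.report["sbp"]["bias"] == pytest.approx(0.0, abs=1e-6)

    def test_row_order_invariance(self):
        model = toy_cohort(n=12, seed=6, noise=0.02)
        res = cross_validate(model, seed=1, alphas=[1e-4])
        perm = np.random.default_rng(0).permutation(12)
        shuffled = BPRegressionModel(
            model.features[perm],
            model.sbp_ref[perm],
            model.dbp_ref[perm],
            subject_ids=model.subject_ids[perm],
        )
        res2 = cross_validate(shuffled, seed=1, alphas=[1e-4])
        pd.testing.assert_frame_equal(res.predictions, res2.predictions)

    def test_holdout_features_only_affect_own_prediction(self):
        """Corrupting one holdout subject's features leaves its fold-mate's
        prediction unchanged (the fold's model never saw either subject)."""
        model = toy_cohort(n=12, seed=8, noise=0.02)
        base = cross_validate(model, seed=2, alphas=[1e-4])
        victim, mate = base.folds[0]
        idx = int(np.where(model.subject_ids == victim)[0][0])
        corrupted = model.features.copy()
        corrupted[idx] = np.clip(corrupted[idx] + 0.5, 0, 1)
        res2 = cross_validate(
            BPRegressionModel(
                corrupted, model.sbp_ref, model.dbp_ref, model.subject_ids
            ),
            seed=2,
            alphas=[1e-4],
        )
        a = base.predictions.set_index("subject_id")
        b = res2.predictions.set_index("subject_id")
        assert not np.allclose(
            a.loc[victim, "sbp_hat"], b.loc[victim, "sbp_hat"]
        )
        for col in ("sbp_hat", "mbp_hat", "dbp_hat"):
            assert a.loc[mate, col] == pytest.approx(b.loc[mate, col], abs=1e-12)

    def test_too_small_fold_rejected(self):
        model = toy_cohort(n=4)
        with pytest.raises(FitError):
            cross_validate(model)

    def test_summary_mentions_folds_and_targets(self):
        model = toy_cohort(n=12, seed=9, noise=0.02)
        res = cross_validate(model, seed=0, alphas=[1e-4])
        text = res.summary()
        assert "6-fold" in text and "SBP" in text and "DBP" in text


class TestResultsSerialization:
    def test_json_round_trip(self, tmp_path):
        model = toy_cohort(n=16, seed=10, noise=0.02)
        res = model.fit()
        path = tmp_path / "model.json"
        res.save(path)
        loaded = BPRegressionResults.load(path)
        X = model.features
        pd.testing.assert_frame_equal(res.predict(X), loaded.predict(X))

    def test_summary_text(self):
        res = toy_cohort(n=16, seed=11).fit()
        text = res.summary()
        assert "LASSO" in text and "alpha" in text and "DBP" in text


class TestParameterRecovery:
    def test_synthetic_cohort_recovery(self):
        """Headline property: on the default synthetic cohort (n=60, seed 7)
        leave-two-out validation recovers SBP with MAE < 8 mmHg and DBP with
        MAE < 6 mmHg — the same order as cuff-grade agreement."""
        sessions = synth.synth_cohort(60, seed=7, fidelity="signal")
        table = pipeline.cohort_table(sessions)
        assert int(table["retained"].sum()) == 60
        model = pipeline.retained_model(table)
        res = cross_validate(model, seed=0)
        assert res.report["sbp"]["mae"] < 8.0
        assert res.report["dbp"]["mae"] < 6.0
        assert abs(res.report["sbp"]["bias"]) < 3.0
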