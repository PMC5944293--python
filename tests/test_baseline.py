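import math

import numpy as np
import pytest
from scipy import stats

from gazedev import GazePair, GazeSession, ProtocolConfig
from gazedev.baseline import (
    BaselineModel,
    GaussianTargetModel,
    classify_subject,
    density,
    deviation_vectors,
    fit_baseline,
    fit_target_model,
    learn_thresholds,
    log_density,
)
from gazedev.simulate import CohortSpec, simulate_cohort

TRUE_COV = np.array(
    [
        [4.0, 1.2, 0.5, 0.0],
        [1.2, 3.0, 0.0, 0.4],
        [0.5, 0.0, 2.0, 0.6],
        [0.0, 0.4, 0.6, 1.5],
    ]
) * 1e-4  # deviation-vector scale: a few hundredths of screen width
TRUE_MEAN = np.array([0.01, -0.005, 0.002, 0.0])


def make_model(mean=None, cov=None, alpha=None, beta=None):
    return GaussianTargetModel(
        target_index=1,
        mean=np.zeros(4) if mean is None else mean,
        cov=np.eye(4) if cov is None else cov,
        alpha=alpha,
        beta=beta,
    )


class TestDeviationVectors:
    def test_signed_target_minus_gaze_convention(self):
        protocol = ProtocolConfig()
        p = GazePair(target_index=5, sample_index=1, left=(0.45, 0.52), right=(0.6, 0.5), timestamp=0.1)
        s = GazeSession(subject_id="s", pairs=[p], protocol=protocol)
        vecs = deviation_vectors(s)
        np.testing.assert_allclose(vecs[5][0], [0.05, -0.02, -0.1, 0.0], atol=1e-12)
        assert all(len(vecs[j]) == 0 for j in range(1, 10) if j != 5)


class TestFitTargetModel:
    def test_parameter_recovery_on_simulated_vectors(self):
        rng = np.random.default_rng(31)
        n = 5000
        draws = rng.multivariate_normal(TRUE_MEAN, TRUE_COV, size=n)
        model = fit_target_model(draws, target_index=1)
        se = np.sqrt(np.diag(TRUE_COV) / n)
        np.testing.assert_array_less(np.abs(model.mean - TRUE_MEAN), 3 * se)
        scale = np.abs(TRUE_COV).max()
        assert np.abs(model.cov - TRUE_COV).max() < 0.1 * scale

    def test_identical_vectors_regularized_to_finite_density(self):
        draws = np.tile([0.01, 0.02, -0.01, 0.0], (10, 1))
        model = fit_target_model(draws, target_index=1)
        val = density(draws[0], model)
        assert np.isfinite(val) and val > 0

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_target_model(np.zeros((2, 4)), target_index=1)


class TestDensity:
    def test_mode_with_identity_covariance(self):
        model = make_model()
        assert density(np.zeros(4), model) == pytest.approx(1.0 / (4 * math.pi**2), abs=1e-12)

    def test_decreases_along_rays_from_mean(self):
        rng = np.random.default_rng(32)
        model = make_model(mean=TRUE_MEAN, cov=TRUE_COV)
        for _ in range(20):
            direction = rng.normal(size=4)
            radii = np.linspace(0.0, 0.1, 25)
            vals = np.array(
                [density(TRUE_MEAN + r * direction, model) for r in radii]
            )
            assert np.all(np.diff(vals) < 0)

    def test_agrees_with_scipy_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(1000):
            scale = rng.uniform(0.01, 1)
            a = rng.normal(size=(6, 4))
            cov = (a.T @ a / 6 + 1e-3 * np.eye(4)) * scale**2
            mean = rng.normal(size=4) * 0.05
            model = make_model(mean=mean, cov=cov)
            u = mean + rng.normal(size=4) * scale  # within a few sigma
            expected = stats.multivariate_normal(mean=mean, cov=cov).logpdf(u)
            assert log_density(u, model) == pytest.approx(expected, abs=1e-10)

    def test_integrates_to_one_importance_check(self):
        model = make_model(mean=TRUE_MEAN, cov=TRUE_COV)
        rng = np.random.default_rng(34)
        proposal_cov = 4.0 * TRUE_COV
        draws = rng.multivariate_normal(TRUE_MEAN, proposal_cov, size=200_000)
        q = stats.multivariate_normal(mean=TRUE_MEAN, cov=proposal_cov).pdf(draws)
        p = np.asarray(density(draws, model))
        integral = float(np.mean(p / q))
        assert integral == pytest.approx(1.0, rel=0.02)


def single_target_session(vectors, target_index=1, subject_id="s", label="unknown"):
    """Session whose deviation vectors at one target equal ``vectors``."""
    protocol = ProtocolConfig()
    tx, ty = protocol.target(target_index).position
    pairs = [
        GazePair(
            target_index=target_index,
            sample_index=i + 1,
            left=(tx - u[0], ty - u[1]),
            right=(tx - u[2], ty - u[3]),
            timestamp=(i + 1) / 60,
        )
        for i, u in enumerate(np.atleast_2d(vectors))
    ]
    return GazeSession(subject_id=subject_id, label=label, pairs=pairs, protocol=protocol)


def thresholded_models(alpha=1e-6, beta=0.5):
    return {
        j: GaussianTargetModel(
            target_index=j, mean=np.zeros(4), cov=np.eye(4) * 1e-4, alpha=alpha, beta=beta
        )
        for j in range(1, 10)
    }


class TestClassifySubject:
    def full_session(self, u_by_target):
        protocol = ProtocolConfig()
        pairs = []
        for j in range(1, 10):
            tx, ty = protocol.target(j).position
            for i, u in enumerate(np.atleast_2d(u_by_target[j])):
                pairs.append(
                    GazePair(
                        target_index=j,
                        sample_index=i + 1,
                        left=(tx - u[0], ty - u[1]),
                        right=(tx - u[2], ty - u[3]),
                        timestamp=(i + 1) / 60,
                    )
                )
        return GazeSession(subject_id="s", pairs=pairs, protocol=protocol)

    def test_all_pairs_at_mode_is_normal(self):
        models = thresholded_models(alpha=1e-2, beta=0.5)
        session = self.full_session({j: np.zeros((10, 4)) for j in range(1, 10)})
        result = classify_subject(session, models)
        assert result.label == "normal"
        assert not any(result.target_strabismic.values())

    def test_single_bad_target_flags_subject(self):
        models = thresholded_models(alpha=1e-2, beta=0.5)
        u = {j: np.zeros((10, 4)) for j in range(1, 10)}
        u[7] = np.full((10, 4), 0.2)  # far tail at one target only
        result = classify_subject(self.full_session(u), models)
        assert result.label == "strabismic"
        assert result.target_strabismic[7]
        assert sum(result.target_strabismic.values()) == 1

    def test_proportion_exactly_at_beta_is_strabismic(self):
        # 5 of 10 pairs normal -> proportion == beta == 0.5, strict > fails.
        models = thresholded_models(alpha=1e-2, beta=0.5)
        u = {j: np.zeros((10, 4)) for j in range(1, 10)}
        u[3] = np.vstack([np.zeros((5, 4)), np.full((5, 4), 0.2)])
        result = classify_subject(self.full_session(u), models)
        assert result.target_normal_proportion[3] == 0.5
        assert result.target_strabismic[3]
        assert result.label == "strabismic"

    def test_missing_target_counts_as_strabismic(self):
        models = thresholded_models(alpha=1e-2, beta=0.5)
        session = single_target_session(np.zeros((10, 4)), target_index=1)
        result = classify_subject(session, models)
        assert result.label == "strabismic"
        assert not result.target_strabismic[1]
        assert all(result.target_strabismic[j] for j in range(2, 10))

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(35)
        u = {j: rng.normal(scale=0.01, size=(20, 4)) for j in range(1, 10)}
        session = self.full_session(u)
        models_low = thresholded_models(alpha=1e-3, beta=0.5)
        result_low = classify_subject(session, models_low)
        for factor in (10.0, 1e3, 1e6):
            models_high = {
                j: GaussianTargetModel(
                    target_index=j, mean=m.mean, cov=m.cov,
                    alpha=m.alpha * factor, beta=m.beta,
                )
                for j, m in models_low.items()
            }
            result_high = classify_subject(session, models_high)
            for j in range(1, 10):
                # raising alpha can only flip targets toward strabismic
                assert result_high.target_strabismic[j] >= result_low.target_strabismic[j]
            if result_low.label == "strabismic":
                assert result_high.label == "strabismic"


class TestLearnThresholds:
    def test_separable_cohort_reaches_perfect_training_accuracy(self, separable_cohort):
        model = fit_baseline(separable_cohort)
        preds = [model.classify(s).label for s in separable_cohort]
        truth = [s.label for s in separable_cohort]
        assert preds == truth

    def test_thresholds_lie_on_the_search_grid(self, separable_cohort):
        model = fit_baseline(separable_cohort)
        beta_grid = {round(0.05 * k, 2) for k in range(1, 20)}
        for m in model.models.values():
            assert m.alpha > 0
            assert round(m.beta, 2) in beta_grid

    def test_deterministic(self, separable_cohort):
        a = fit_baseline(separable_cohort)
        b = fit_baseline(separable_cohort)
        for j in range(1, 10):
            assert a.models[j].alpha == b.models[j].alpha
            assert a.models[j].beta == b.models[j].beta
            np.testing.assert_array_equal(a.models[j].mean, b.models[j].mean)

    def test_single_class_training_rejected(self):
        sessions = simulate_cohort(CohortSpec(n_normal=3, n_strabismic=0, seed=36))
        with pytest.raises(ValueError, match="both"):
            fit_baseline(sessions)


class TestSerialization:
    def test_model_round_trip(self, separable_cohort, tmp_path):
        model = fit_baseline(separable_cohort)
        path = tmp_path / "baseline.json"
        model.save(path)
        back = BaselineModel.load(path)
        for j in range(1, 10):
            np.testing.assert_array_equal(back.models[j].mean, model.models[j].mean)
            np.testing.assert_array_equal(back.models[j].cov, model.models[j].cov)
            assert back.models[j].alpha == model.models[j].alpha
            assert back.models[j].beta == model.models[j].beta
        s = separable_cohort[0]
        assert back.classify(s).label == model.classify(s).label
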