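import numpy as np
import pytest
from scipy.stats import poisson

from soctouch import glm as G
from soctouch.session import BIN_WIDTH
from soctouch.synth import GeneratorParams, generate_session, make_beta


class TestPredictorMatrix:
    def test_column_count_four_recordings(self, simple_session):
        pm = G.build_predictor_matrix(simple_session, "u0", include_sex=True)
        assert len(pm.names) == 1 + 11 + 3 + 1 + 1 == 17
        assert pm.names[-2:] == ["touch", "sex"]

    def test_touch_only_variant_drops_sex(self, simple_session):
        pm = G.build_predictor_matrix(simple_session, "u0", include_sex=False)
        assert "sex" not in pm.names and len(pm.names) == 16

    def test_single_isolated_spike_history(self):
        """A spike in the 'previous 3-4 ms' window sets h_4 and no other
        1-ms history column."""
        counts = np.zeros(200, dtype=int)
        counts[100] = 1
        H = G.history_matrix(counts)
        row = H[104]  # four lags later
        assert row[3] == 1
        assert row[[0, 1, 2, 4]].sum() == 0

    def test_coarse_windows_match_bruteforce(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(0.08, 3000)
        H = G.history_matrix(counts)
        for i in rng.integers(200, 3000, 25):
            for j, (a, b) in enumerate(G.HISTORY_COARSE_WINDOWS):
                lags = np.arange(a, b + 1)
                idx = i - lags
                idx = idx[idx >= 0]
                assert H[i, 5 + j] == counts[idx].sum()

    def test_history_is_causal(self):
        counts = np.zeros(300, dtype=int)
        counts[150] = 3
        H = G.history_matrix(counts)
        assert H[:151].sum() == 0  # nothing before or at the spike's own bin
        assert H[151].sum() == 3   # visible from the next bin on

    def test_sex_column_marks_male_touch_bins_only(self, glm_session):
        sess, _ = glm_session
        pm = G.build_predictor_matrix(sess, "driven", include_sex=True)
        sex = pm.X[:, pm.sex_col]
        touch = pm.X[:, pm.touch_col]
        assert np.all(sex <= touch)
        male = pm.partner_sex[pm.partner_code[sex > 0]] == "M"
        assert male.all()


class TestLogLikelihood:
    def test_constant_rate_all_zero_counts(self):
        """lambda = 1000/s over n 1-ms bins, no spikes: LL = -n."""
        n = 500
        X = np.ones((n, 1))
        y = np.zeros(n)
        ll = G.log_likelihood([np.log(1000.0)], X, y)
        assert ll == pytest.approx(-n, rel=1e-12)

    def test_matches_per_bin_poisson_pmf(self):
        rng = np.random.default_rng(3)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(0, 0.3, n)])
        beta = np.array([2.0, 0.5])
        y = rng.poisson(0.05, n).astype(float)
        mu = np.exp(X @ beta) * BIN_WIDTH
        expected = poisson.logpmf(y, mu).sum()
        assert G.log_likelihood(beta, X, y) == pytest.approx(expected, rel=1e-9)

    def test_incremental_spike_identity(self):
        """Adding one spike to bin i changes LL by log(lambda_i dt) - log(y_i + 1)."""
        rng = np.random.default_rng(4)
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.5, 0.2])
        y = rng.poisson(0.1, n).astype(float)
        i = 17
        before = G.log_likelihood(beta, X, y)
        y2 = y.copy()
        y2[i] += 1
        after = G.log_likelihood(beta, X, y2)
        lam_dt = np.exp(X[i] @ beta) * BIN_WIDTH
        assert after - before == pytest.approx(
            np.log(lam_dt) - np.log(y[i] + 1), rel=1e-9
        )


class TestFit:
    def test_constant_only_model_recovers_log_rate(self):
        rng = np.random.default_rng(6)
        lam = 7.0
        n = 200_000
        y = rng.poisson(lam * BIN_WIDTH, n).astype(float)
        fit = G.fit_poisson_glm(np.ones((n, 1)), y, names=["const"])
        assert fit.beta[0] == pytest.approx(np.log(y.mean() / BIN_WIDTH), abs=1e-9)
        assert fit.beta[0] == pytest.approx(np.log(lam), abs=0.09)

    def test_matches_damped_irls_oracle(self, glm_session):
        """Newton optimum equals an independent IRLS fit to 1e-6."""
        sess, _ = glm_session
        model = G.TouchGLM(sess, "driven")
        res = model.fit()
        X, y = model.pm.X, model.pm.y

        def ll(b):
            mu = np.exp(X @ b) * BIN_WIDTH
            return y @ np.log(mu) - mu.sum()

        beta = np.zeros(X.shape[1])
        beta[0] = np.log(y.mean() / BIN_WIDTH)
        cur = ll(beta)
        for _ in range(200):
            eta = X @ beta
            mu = np.exp(eta) * BIN_WIDTH
            z = eta + (y - mu) / mu
            w = np.sqrt(mu)
            b_new, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
            step = b_new - beta
            t = 1.0
            while ll(beta + t * step) < cur and t > 1e-10:
                t *= 0.5
            beta = beta + t * step
            new = ll(beta)
            if new - cur < 1e-14 * abs(cur):
                break
            cur = new
        assert np.max(np.abs(beta - res.fit.beta)) < 1e-6

    def test_mle_beats_generating_truth(self, glm_session):
        sess, betas = glm_session
        model = G.TouchGLM(sess, "driven")
        res = model.fit()
        truth = np.array([betas["driven"].get(n, 0.0) for n in model.pm.names])
        ll_truth = G.log_likelihood(truth, model.pm.X, model.pm.y)
        assert res.llf >= ll_truth

    def test_nested_models_likelihood_ordering(self, glm_session):
        sess, _ = glm_session
        full = G.TouchGLM(sess, "driven", include_sex=True).fit()
        reduced = G.TouchGLM(sess, "driven", include_sex=False).fit()
        assert full.llf >= reduced.llf - 1e-6

    def test_parameter_recovery_short_sessions(self):
        """beta_touch recovered without systematic bias on 240-s sessions."""
        errs = []
        for seed in range(6):
            sess = generate_session(
                GeneratorParams(seed=None, n_blocks=4, block_length=60.0),
                {"u": make_beta(np.log(10.0), touch=0.5, sex=0.3)},
                seed=300 + seed,
            )
            res = G.TouchGLM(sess, "u").fit()
            errs.append(res.params["touch"] - 0.5)
        assert abs(np.mean(errs)) < 0.12


class TestShuffleTests:
    def test_plus_one_estimator_bounds(self):
        assert G._plus_one_p(0.0, np.full(99, 1.0)) == 1.0
        assert G._plus_one_p(1.0, np.zeros(99)) == pytest.approx(0.01)

    def test_driven_unit_detected_null_unit_not(self, glm_session):
        sess, _ = glm_session
        r_driven = G.shuffle_touch_test(sess, "driven", n_shuffles=30, seed=1)
        assert r_driven.p_value <= 1 / 31 + 1e-9
        r_null = G.shuffle_touch_test(sess, "null", n_shuffles=30, seed=2)
        assert r_null.p_value > 0.05

    def test_sex_shuffle_detects_sex_effect(self, glm_session):
        sess, _ = glm_session
        r = G.shuffle_sex_test(sess, "driven", n_shuffles=30, seed=3)
        assert r.p_value < 0.1  # 4+4 partners give real power

    def test_single_sex_partners_returns_one(self):
        sess = generate_session(
            GeneratorParams(
                seed=None, n_blocks=2, block_length=40.0,
                partners=(("f1", "F"), ("f2", "F")),
            ),
            {"u": make_beta(np.log(8.0))},
            seed=9,
        )
        with pytest.warns(UserWarning, match="one sex"):
            r = G.shuffle_sex_test(sess, "u", n_shuffles=10, seed=0)
        assert r.p_value == 1.0

    def test_partner_level_label_assignments(self, simple_session):
        """2+2 partners admit only C(4,2)=6 distinct label patterns."""
        pm = G.build_predictor_matrix(simple_session, "u0", include_sex=True)
        rng = np.random.default_rng(0)
        labels = (pm.partner_sex == "M").astype(float)
        assert labels.size == 4
        seen = {tuple(rng.permutation(labels)) for _ in range(200)}
        assert len(seen) <= 6


class TestClassification:
    @pytest.mark.parametrize(
        "p_touch,p_sex,label",
        [
            (0.6, 0.03, "sex_touch"),
            (0.03, 0.5, "touch"),
            (0.5, 0.5, "nonsignificant"),
            (0.03, 0.03, "sex_touch"),
        ],
    )
    def test_label_rules(self, p_touch, p_sex, label):
        assert G.classify(p_touch, p_sex) == label


class TestModelPSTH:
    def test_flat_when_no_touch_modulation(self, glm_session):
        sess, _ = glm_session
        res = G.TouchGLM(sess, "null").fit()
        out = G.model_psth(res, sess, n_reps=6, seed=0)
        for sex, r in out.items():
            cv = r.rate.std() / r.rate.mean()
            assert cv < 0.3

    def test_sex_effect_scales_male_trace(self, glm_session):
        sess, _ = glm_session
        res = G.TouchGLM(sess, "driven").fit()
        out = G.model_psth(res, sess, n_reps=6, seed=1)
        in_touch = (out["M"].times > 0.2) & (out["M"].times < 0.8)
        ratio = out["M"].rate[in_touch].mean() / out["F"].rate[in_touch].mean()
        assert ratio > 1.1  # beta_sex > 0 in the generator
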