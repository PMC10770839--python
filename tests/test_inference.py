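import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

from iterlearn.inference import (
    ModelSpec,
    SamplerConfig,
    _BetaRegProblem,
    compare_waic,
    credible_interval,
    fit_model,
    posterior_predictive,
    squeeze_to_open_interval,
    transform_response,
    waic,
)
from iterlearn.synthetic_chains import generate_betareg_oracle

FAST = SamplerConfig(chains=2, warmup=250, draws=250, seed=5)


def small_oracle(seed, **kwargs):
    rng = np.random.default_rng(seed)
    defaults = dict(n_chains=6, n_stimuli=8, generations=6)
    defaults.update(kwargs)
    return generate_betareg_oracle(rng=rng, **defaults)


class TestSqueeze:
    @pytest.mark.parametrize(
        "y, n, expected", [(1.0, 100, 0.995), (0.0, 100, 0.005), (0.5, 7, 0.5)]
    )
    def test_closed_form(self, y, n, expected):
        assert squeeze_to_open_interval(y, n) == pytest.approx(expected)

    def test_order_preserving_and_open(self):
        y = np.linspace(0, 1, 11)
        z = squeeze_to_open_interval(y, 50)
        assert (np.diff(z) > 0).all() and (z > 0).all() and (z < 1).all()

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            squeeze_to_open_interval(0.5, 0)


class TestTransformResponse:
    @staticmethod
    def measure_frame(**cols):
        n = len(next(iter(cols.values())))
        base = dict(
            experiment_id=["e"] * n,
            condition=[0] * n,
            chain_id=[1] * n,
            generation=list(range(1, n + 1)),
            trial_index=[1] * n,
            stimulus_id=[1] * n,
        )
        base.update(cols)
        return pd.DataFrame(base)

    def test_depth_scaled_by_max_depth_before_squeeze(self):
        frame = self.measure_frame(depth=[2, 0, 3])
        table, meta = transform_response(frame, "depth")
        n = len(table)
        assert table["y"].iloc[0] == pytest.approx(
            squeeze_to_open_interval(2 / 3, n)
        )
        assert "depth / 3" in meta["transformation"]

    def test_perfect_accuracy_strictly_below_one(self):
        frame = self.measure_frame(accuracy=[1.0, 0.5, 0.25])
        table, meta = transform_response(frame, "accuracy")
        assert (table["y"] < 1).all() and (table["y"] > 0).all()
        assert meta["transformation"] == "boundary squeeze"

    def test_ratio_above_one_clipped_with_warning(self):
        frame = self.measure_frame(compression_ratio=[1.08, 0.5, 0.6])
        with pytest.warns(UserWarning, match="clipped"):
            table, meta = transform_response(frame, "compression_ratio")
        assert meta["clipped_above_one"] == 1
        assert (table["y"] < 1).all()

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            transform_response(self.measure_frame(accuracy=[0.5]), "speed")


class TestCredibleInterval:
    def test_standard_normal_matches_analytic_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = credible_interval(draws, 0.89)
        # Phi^-1(0.945) = 1.5982
        assert lo == pytest.approx(-1.5982, abs=0.03)
        assert hi == pytest.approx(1.5982, abs=0.03)

    def test_constant_draws(self):
        assert credible_interval(np.full(500, 3.3)) == (3.3, 3.3)

    def test_affine_equivariance(self):
        draws = np.random.default_rng(1).standard_normal(5000)
        lo, hi = credible_interval(draws)
        lo2, hi2 = credible_interval(2.5 * draws + 1)
        assert lo2 == pytest.approx(2.5 * lo + 1) and hi2 == pytest.approx(2.5 * hi + 1)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        tab = small_oracle(3, n_chains=4, n_stimuli=5, generations=4)
        for interaction in (False, True):
            prob = _BetaRegProblem(tab, ModelSpec(interaction=interaction))
            rng = np.random.default_rng(9)
            for _ in range(3):
                q = rng.normal(0, 0.4, prob.dim)
                num = approx_fprime(q, lambda x: prob.logp_grad(x)[0], 1e-6)
                ana = prob.logp_grad(q)[1]
                assert np.allclose(num, ana, rtol=1e-3, atol=1e-2)


class TestWaic:
    def test_hand_computed_fixture(self):
        """5 observations x 4 draws, checked against an explicit
        spreadsheet-style computation."""
        ll = np.array(
            [
                [-1.0, -2.0, -0.5, -1.5, -3.0],
                [-1.2, -1.8, -0.7, -1.4, -2.5],
                [-0.9, -2.2, -0.6, -1.6, -3.2],
                [-1.1, -1.9, -0.4, -1.3, -2.8],
            ]
        )
        s, n = ll.shape
        expected_lppd, expected_p = 0.0, 0.0
        pointwise = []
        for i in range(n):
            col = [ll[s_][i] for s_ in range(s)]
            lppd_i = math.log(sum(math.exp(v) for v in col) / s)
            mean = sum(col) / s
            p_i = sum((v - mean) ** 2 for v in col) / (s - 1)
            expected_lppd += lppd_i
            expected_p += p_i
            pointwise.append(-2 * (lppd_i - p_i))
        res = waic(ll)
        assert res.waic == pytest.approx(-2 * (expected_lppd - expected_p), abs=1e-9)
        assert res.lppd == pytest.approx(expected_lppd, abs=1e-9)
        assert res.p_waic == pytest.approx(expected_p, abs=1e-9)
        mean_pw = sum(pointwise) / n
        var_pw = sum((v - mean_pw) ** 2 for v in pointwise) / (n - 1)
        assert res.se == pytest.approx(math.sqrt(n * var_pw), abs=1e-9)

    def test_agrees_with_arviz_up_to_variance_convention(self):
        """Cross-check against arviz; the only expected difference is the
        p_waic variance estimator (we use the sample variance with ddof=1,
        the R convention; arviz uses ddof=0), which shrinks as 1/draws."""
        import arviz as az

        s = 200
        ll = np.random.default_rng(2).normal(-1.0, 0.3, size=(2, s // 2, 30))
        ours = waic(ll.reshape(s, 30))
        idata = az.from_dict(log_likelihood={"y": ll})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = float(az.waic(idata, scale="deviance").elpd_waic)
        ddof_gap = 2 * ours.p_waic / s  # p_waic * (1 - (s-1)/s) * 2
        assert ours.waic == pytest.approx(theirs + ddof_gap, abs=1e-9)

    def test_zero_posterior_variance_gives_zero_p_waic(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.3]), (6, 1))
        assert waic(ll).p_waic == pytest.approx(0.0)

    def test_non_finite_loglik_rejected(self):
        with pytest.raises(ValueError):
            waic(np.array([[0.0, -np.inf]]))


@pytest.fixture(scope="module")
def null_fits():
    """Model 1 and Model 2 fitted to interaction-free data."""
    tab = small_oracle(21, beta_interaction=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        f1 = fit_model(tab, ModelSpec(interaction=False), FAST)
        f2 = fit_model(tab, ModelSpec(interaction=True), FAST)
    return f1, f2


class TestFitAndCompare:
    def test_fit_is_seed_reproducible(self):
        tab = small_oracle(4, n_chains=4, n_stimuli=4, generations=4)
        cfg = SamplerConfig(chains=2, warmup=150, draws=150, seed=42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            s1 = fit_model(tab, ModelSpec(), cfg).summary()
            s2 = fit_model(tab, ModelSpec(), cfg).summary()
        pd.testing.assert_frame_equal(s1, s2)

    def test_comparing_fit_with_itself_is_zero(self, null_fits):
        f1, _ = null_fits
        cmp = compare_waic(f1, f1)
        assert cmp.d_waic == 0.0 and cmp.d_se == 0.0

    def test_null_interaction_small_dwaic(self, null_fits):
        f1, f2 = null_fits
        cmp = compare_waic(f1, f2)
        assert cmp.d_se >= 0
        # without a true interaction the models should be within ~2 dSE
        assert abs(cmp.d_waic) < max(4.0, 2.5 * cmp.d_se)

    def test_true_interaction_favors_model_2(self):
        tab = small_oracle(22, beta_interaction=0.12, phi=60.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            f1 = fit_model(tab, ModelSpec(interaction=False), FAST)
            f2 = fit_model(tab, ModelSpec(interaction=True), FAST)
        cmp = compare_waic(f1, f2)
        assert cmp.waic_2 < cmp.waic_1

    def test_mismatched_observation_sets_rejected(self, null_fits):
        f1, _ = null_fits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            other = fit_model(
                small_oracle(5, n_chains=4, n_stimuli=4, generations=3),
                ModelSpec(),
                SamplerConfig(chains=2, warmup=100, draws=100, seed=1),
            )
        with pytest.raises(ValueError):
            compare_waic(f1, other)


class TestParameterRecovery:
    def test_generation_effect_covered_by_89_interval(self):
        """The true generation coefficient falls inside its 89% interval in
        roughly 89% of replications (binomial band at 20 reps)."""
        true_beta = 0.15
        hits = 0
        for rep in range(20):
            tab = small_oracle(
                100 + rep, n_chains=4, n_stimuli=6, generations=5,
                beta_generation=true_beta,
            )
            cfg = SamplerConfig(chains=2, warmup=200, draws=200, seed=1000 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_model(tab, ModelSpec(interaction=False), cfg)
            lo, hi = credible_interval(fit.flat("Generation"), 0.89)
            hits += lo <= true_beta <= hi
        # Binomial(20, 0.89): P(X >= 14) > 0.99
        assert hits >= 14


class TestPosteriorPredictive:
    def test_samples_on_beta_support_and_mode_granularity(self, null_fits):
        _, f2 = null_fits
        ps = posterior_predictive(f2, condition=0, generation=3, n_draws=500)
        assert ((ps.samples > 0) & (ps.samples < 1)).all()
        assert ps.mode_bin == pytest.approx(round(ps.mode_bin / 0.05) * 0.05)

    def test_predictive_mean_tracks_observed_mean(self):
        tab = small_oracle(
            33, intercept=0.0, beta_condition=0.0, beta_generation=0.0,
            sd_chain=0.1, sd_stimulus=0.1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit = fit_model(tab, ModelSpec(interaction=False), FAST)
        ps = posterior_predictive(
            fit, condition=0, generation=3, n_draws=4000,
            rng=np.random.default_rng(0),
        )
        assert ps.samples.mean() == pytest.approx(tab["y"].mean(), abs=0.05)

    def test_extrapolation_warns(self, null_fits):
        _, f2 = null_fits
        with pytest.warns(UserWarning, match="extrapolating"):
            posterior_predictive(f2, condition=0, generation=99, n_draws=50)
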