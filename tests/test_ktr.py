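"""Rate fitting: hazard closed forms, likelihood, KS, bootstrap, rescaling."""

import warnings

import numpy as np
import pytest
from scipy import integrate

from unbindkit.escape import EscapeTimeSet, GroundTruthRates, sample_escape_times
from unbindkit.ktr import (
    VMBModel,
    bootstrap_rates,
    cumulative_hazard,
    fit_mle,
    fit_rates,
    fit_vmb,
    hyperdynamics_rescale,
    ks_validate,
    log_likelihood,
    survival,
)
from unbindkit.metad import BiasTrace


class TestVMBFit:
    def test_exact_series_recovered(self):
        t = np.linspace(0.0, 30.0, 200)
        v = 3.0 * np.log1p(0.5 * t)
        m = fit_vmb(t, v, t_c=25.0)
        assert m.a == pytest.approx(3.0, abs=1e-6)
        assert m.b == pytest.approx(0.5, abs=1e-6)

    def test_zero_series_degenerate(self):
        t = np.linspace(0.0, 10.0, 50)
        with pytest.warns(UserWarning, match="zero"):
            m = fit_vmb(t, np.zeros(50), t_c=8.0)
        assert m.a == 0.0

    def test_plateau_continuity(self):
        m = VMBModel(a=2.0, b=0.3, t_c=12.0)
        assert m.value(12.0) == pytest.approx(m.plateau, rel=1e-14)
        assert m.value(50.0) == m.value(12.0)


class TestHazard:
    def test_closed_form_matches_quadrature(self, rng):
        for _ in range(25):
            model = VMBModel(
                a=rng.uniform(0.0, 4.0),
                b=rng.uniform(0.05, 3.0),
                t_c=rng.uniform(1.0, 30.0),
            )
            k0 = 10 ** rng.uniform(-4, 0)
            gamma = rng.uniform(0.0, 1.0)
            beta = rng.uniform(0.5, 2.0)
            t = rng.uniform(0.1, 60.0)
            closed = cumulative_hazard(t, k0, gamma, model, beta)
            quad, _ = integrate.quad(
                lambda s: k0 * np.exp(gamma * beta * model.value(s)),
                0.0, t, limit=400, epsabs=1e-14, epsrel=1e-11,
                points=[model.t_c] if model.t_c < t else None,
            )
            assert closed == pytest.approx(quad, rel=1e-8)

    def test_logarithmic_special_case(self):
        # c = gamma beta a = -1 is unreachable with gamma,a >= 0;
        # verify the guarded branch directly against quadrature
        model = VMBModel(a=1.0, b=0.7, t_c=10.0)
        closed = cumulative_hazard(5.0, 1.0, -1.0, model, 1.0)
        quad, _ = integrate.quad(
            lambda s: np.exp(-model.value(s)), 0.0, 5.0, limit=400
        )
        assert closed == pytest.approx(quad, rel=1e-8)

    def test_survival_limits(self):
        model = VMBModel(a=2.0, b=1.0, t_c=10.0)
        assert survival(0.0, 0.1, 0.7, model) == 1.0
        t = np.linspace(0.0, 100.0, 200)
        s = survival(t, 0.1, 0.7, model)
        assert np.all(np.diff(s) < 0)
        assert s[-1] < 1e-6

    def test_zero_bias_is_exponential(self):
        model = VMBModel(a=0.0, b=1.0, t_c=10.0)
        t = np.array([0.5, 1.0, 5.0])
        np.testing.assert_allclose(
            survival(t, 0.3, 0.9, model), np.exp(-0.3 * t), rtol=1e-14
        )


class TestLikelihood:
    def test_duplication_doubles_loglik(self):
        model = VMBModel(a=2.0, b=1.0, t_c=10.0)
        d1 = EscapeTimeSet(times=[1.0, 2.0, 7.0], events=[True, True, False])
        d2 = EscapeTimeSet(
            times=[1.0, 2.0, 7.0] * 2, events=[True, True, False] * 2
        )
        l1 = log_likelihood(0.1, 0.5, d1, model)
        l2 = log_likelihood(0.1, 0.5, d2, model)
        assert l2 == pytest.approx(2.0 * l1, rel=1e-14)

    def test_zero_bias_mle_is_exponential_mle(self, rng):
        times = rng.exponential(scale=4.0, size=300)
        data = EscapeTimeSet(times=times, events=np.ones(300, dtype=bool))
        model = VMBModel(a=0.0, b=1.0, t_c=10.0)
        k0, gamma, _, flag = fit_mle(data, model)
        assert flag
        assert k0 == pytest.approx(300 / times.sum(), rel=1e-3)

    def test_truth_beats_wrong_rate_on_large_data(self):
        truth = GroundTruthRates(k0=0.01, gamma=0.7, a=2.5, b=1.0, t_c=15.0)
        data = sample_escape_times(truth, 10_000, horizon=1e4, seed=6)
        model = VMBModel(a=truth.a, b=truth.b, t_c=truth.t_c)
        ll_true = log_likelihood(truth.k0, truth.gamma, data, model)
        ll_bad = log_likelihood(2 * truth.k0, truth.gamma, data, model)
        assert ll_true > ll_bad

    def test_early_censored_records_barely_move_k0(self):
        truth = GroundTruthRates(k0=0.01, gamma=0.7, a=2.5, b=1.0, t_c=15.0)
        data = sample_escape_times(truth, 2_000, horizon=1e4, seed=7)
        model = VMBModel(a=truth.a, b=truth.b, t_c=truth.t_c)
        k0_base, _, _, _ = fit_mle(data, model)
        padded = EscapeTimeSet(
            times=np.concatenate([data.times, np.full(50, 1e-6)]),
            events=np.concatenate([data.events, np.zeros(50, dtype=bool)]),
        )
        k0_pad, _, _, _ = fit_mle(padded, model)
        assert k0_pad == pytest.approx(k0_base, rel=0.01)


class TestKS:
    def test_wrong_model_strongly_rejected(self, rng):
        times = rng.exponential(scale=1.0, size=100)
        data = EscapeTimeSet(times=times, events=np.ones(100, dtype=bool))
        model = VMBModel(a=0.0, b=1.0, t_c=10.0)
        _, p = ks_validate(data, 10.0, 0.0, model)  # 10x the true rate
        assert p < 0.01

    def test_needs_three_events(self):
        data = EscapeTimeSet(times=[1.0, 2.0], events=[True, True])
        with pytest.raises(ValueError, match="three"):
            ks_validate(data, 1.0, 0.5, VMBModel(a=1.0, b=1.0, t_c=5.0))


class TestBootstrap:
    MODEL = VMBModel(a=0.0, b=1.0, t_c=10.0)

    def test_degenerate_identical_times_zero_width(self):
        data = EscapeTimeSet(times=np.full(20, 2.0),
                             events=np.ones(20, dtype=bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = bootstrap_rates(data, self.MODEL, n_boot=20, seed=1)
        assert b.percentile_30 == pytest.approx(b.percentile_70)

    def test_seeded_determinism(self, rng):
        times = rng.exponential(size=30)
        data = EscapeTimeSet(times=times, events=np.ones(30, dtype=bool))
        b1 = bootstrap_rates(data, self.MODEL, n_boot=30, seed=5)
        b2 = bootstrap_rates(data, self.MODEL, n_boot=30, seed=5)
        assert b1.percentile_30 == b2.percentile_30
        assert b1.percentile_70 == b2.percentile_70

    def test_interval_shrinks_with_sample_size(self):
        truth = GroundTruthRates(k0=2e-3, gamma=0.7, a=3.0, b=1.0, t_c=10.0)
        widths = {41: [], 500: []}
        for seed in range(5):
            for n in (41, 500):
                data = sample_escape_times(truth, n, horizon=200.0,
                                           seed=100 + seed)
                model = VMBModel(a=truth.a, b=truth.b, t_c=truth.t_c)
                k0, _, _, _ = fit_mle(data, model)
                b = bootstrap_rates(data, model, n_boot=50, seed=seed)
                widths[n].append(
                    (b.percentile_70 - b.percentile_30) / k0
                )
        assert np.mean(widths[500]) < np.mean(widths[41])


class TestHyperdynamics:
    def test_zero_bias_identity(self):
        t = np.linspace(0.0, 10.0, 101)
        traces = [BiasTrace(times=t, values=np.zeros(101))] * 3
        data = EscapeTimeSet(times=[2.0, 5.0, 8.0], events=[True] * 3,
                             traces=traces)
        res = hyperdynamics_rescale(data)
        np.testing.assert_allclose(res.rescaled_times, [2.0, 5.0, 8.0],
                                   rtol=1e-12)

    def test_constant_bias_scales_exponentially(self):
        c = 1.5
        t = np.linspace(0.0, 10.0, 101)
        traces = [BiasTrace(times=t, values=np.full(101, c))] * 3
        data = EscapeTimeSet(times=[2.0, 5.0, 8.0], events=[True] * 3,
                             traces=traces)
        res = hyperdynamics_rescale(data, beta=2.0)
        np.testing.assert_allclose(
            res.rescaled_times, np.exp(2.0 * c) * np.array([2.0, 5.0, 8.0]),
            rtol=1e-12,
        )

    def test_agrees_with_ktr_on_ideal_cv_data(self):
        """With gamma = 1 (ideal CV) the rescaled-time rate matches k0."""
        truth = GroundTruthRates(k0=0.05, gamma=1.0, a=2.0, b=1.0, t_c=8.0)
        data = sample_escape_times(truth, 200, horizon=400.0, seed=12)
        fit = fit_rates(data)
        res = hyperdynamics_rescale(data)
        assert 0.5 < res.rate / fit.k0 < 2.0
        assert 0.5 < res.rate / truth.k0 < 2.0

    def test_missing_trace_coverage_rejected(self):
        t = np.linspace(0.0, 1.0, 11)
        traces = [BiasTrace(times=t, values=np.zeros(11))]
        data = EscapeTimeSet(times=[5.0], events=[True], traces=traces)
        with pytest.raises(ValueError, match="ends"):
            hyperdynamics_rescale(data)


class TestFitRates:
    def test_recovery_with_cutoff_scan(self):
        # unbiased timescale comparable to the bias growth: the
        # identifiable regime for joint (k0, gamma) recovery
        truth = GroundTruthRates(k0=1.0, gamma=0.7, a=3.0, b=1.0, t_c=10.0)
        data = sample_escape_times(truth, 500, horizon=50.0, seed=2)
        fit = fit_rates(data)
        assert fit.k0 == pytest.approx(truth.k0, rel=0.15)
        assert fit.gamma == pytest.approx(truth.gamma, abs=0.1)

    def test_needs_five_events(self):
        data = EscapeTimeSet(times=[1.0] * 4, events=[True] * 4)
        with pytest.raises(ValueError, match="five"):
            fit_rates(data)
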