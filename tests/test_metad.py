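"""Well-tempered bias engine: deposition, evaluation, survivor average."""

import numpy as np
import pytest

from unbindkit.langevin import LangevinConfig, integrate_langevin
from unbindkit.metad import (
    BiasTrace,
    Hill,
    MetadParams,
    bias_value,
    deposit_hill,
    run_metad,
    survivor_max_bias,
)
from unbindkit.potentials import DoubleWell1D


def _hill(center, height=1.0, widths=(0.5,), time=0.0):
    return Hill(center=center, widths=widths, height=height, time=time)


class TestBiasValue:
    def test_empty_list_is_zero(self):
        assert bias_value([], [0.3]) == 0.0

    def test_at_center_equals_height(self):
        assert bias_value([_hill((1.0,), 2.5)], [1.0]) == pytest.approx(2.5)

    def test_one_sigma_offset(self):
        h = _hill((0.0,), 2.0, widths=(0.4,))
        assert bias_value([h], [0.4]) == pytest.approx(2.0 * np.exp(-0.5))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            bias_value([_hill((0.0,))], [0.0, 1.0])

    def test_nondecreasing_in_hill_count(self, rng):
        params = MetadParams(height=0.5, sigmas=(0.3,), bias_factor=5.0)
        hills = []
        pt = [0.2]
        prev = 0.0
        for i in range(20):
            deposit_hill(hills, [rng.uniform(-1, 1)], params, float(i))
            v = bias_value(hills, pt)
            assert v >= prev - 1e-15
            prev = v


class TestDepositHill:
    def test_first_hill_full_height(self):
        params = MetadParams(height=1.2, sigmas=(0.1,), bias_factor=20.0)
        hills = []
        h = deposit_hill(hills, [0.0], params, 0.0)
        assert h.height == pytest.approx(1.2)

    def test_height_drops_by_e_at_reference_bias(self):
        params = MetadParams(height=1.0, sigmas=(0.1,), bias_factor=5.0,
                             kT=1.0)
        hills = []
        # build bias V = (gamma-1) kT = 4 at the deposition point
        target = (params.bias_factor - 1.0) * params.kT
        hills.append(_hill((0.0,), target, widths=(0.1,)))
        h = deposit_hill(hills, [0.0], params, 1.0)
        assert h.height == pytest.approx(1.0 / np.e)

    def test_huge_bias_factor_recovers_untempered(self):
        params = MetadParams(height=1.0, sigmas=(0.1,), bias_factor=1e9)
        hills = [_hill((0.0,), 5.0, widths=(0.1,))]
        h = deposit_hill(hills, [0.0], params, 1.0)
        assert h.height == pytest.approx(1.0, abs=1e-8)

    def test_tempering_monotone_when_trapped(self):
        params = MetadParams(height=1.0, sigmas=(0.2,), bias_factor=8.0)
        hills = []
        heights = [deposit_hill(hills, [0.0], params, float(i)).height
                   for i in range(30)]
        assert np.all(np.diff(heights) < 0)


class TestRunMetad:
    def test_zero_height_reduces_to_plain_langevin(self, double_well):
        cfg = LangevinConfig(timestep=0.005, n_steps=4000, seed=9,
                             save_stride=10)
        params = MetadParams(height=0.0, stride_time=0.5, sigmas=(0.15,),
                             bias_factor=10.0)
        run = run_metad(double_well, params, cfg)
        plain = integrate_langevin(double_well, cfg)
        np.testing.assert_array_equal(
            run.trajectory.positions, plain.positions
        )
        assert run.hills == []

    def test_well_tempered_flattening(self):
        """Converged bias approaches -(1 - 1/gamma_wt) F(x) up to a shift."""
        pot = DoubleWell1D(barrier=4.0)
        cfg = LangevinConfig(timestep=0.0025, n_steps=800_000, seed=2,
                             save_stride=10)
        params = MetadParams(height=0.8, stride_time=1.0, sigmas=(0.15,),
                             bias_factor=12.0)
        run = run_metad(pot, params, cfg)
        x = run.trajectory.positions[:, 0]
        cnt, edges = np.histogram(x, bins=24, range=(-1.4, 1.4))
        centers = 0.5 * (edges[:-1] + edges[1:])
        v = np.array([bias_value(run.hills, [c]) for c in centers])
        u = np.array([pot.energy([c]) for c in centers])
        m = cnt > 50
        eff = v[m] + (1.0 - 1.0 / params.bias_factor) * u[m]
        assert eff.max() - eff.min() < 1.0

    def test_bias_accelerates_recrossings(self):
        pot = DoubleWell1D(barrier=10.0)
        cfg = LangevinConfig(timestep=0.005, n_steps=200_000, seed=4,
                             save_stride=10)
        params = MetadParams(height=0.8, stride_time=1.0, sigmas=(0.15,),
                             bias_factor=12.0)

        def count_transitions(x):
            state = np.sign(x[np.abs(x) > 0.5][0])
            n = 0
            for xi in x:
                if xi > 0.5 and state < 0:
                    n, state = n + 1, 1.0
                elif xi < -0.5 and state > 0:
                    n, state = n + 1, -1.0
            return n

        biased = run_metad(pot, params, cfg)
        unbiased = integrate_langevin(pot, cfg)
        n_b = count_transitions(biased.trajectory.positions[:, 0])
        n_u = count_transitions(unbiased.positions[:, 0])
        assert n_b >= 3
        assert n_u <= 1


class TestSurvivorMaxBias:
    def test_identical_monotone_traces_no_escape(self):
        t = np.linspace(0.0, 10.0, 21)
        v = np.sqrt(t)
        traces = [BiasTrace(times=t, values=v) for _ in range(3)]
        s = survivor_max_bias(traces, [20.0, 20.0, 20.0])
        np.testing.assert_allclose(
            s.values, np.interp(s.times, t, v), atol=1e-12
        )

    def test_survivor_rule_drops_escaped_run(self):
        t = np.linspace(0.0, 10.0, 11)
        lo = BiasTrace(times=t, values=np.full_like(t, 1.0))
        hi = BiasTrace(times=t, values=np.full_like(t, 3.0))
        s = survivor_max_bias([lo, hi], [20.0, 5.0])
        before = s.values[s.times <= 5.0]
        after = s.values[s.times > 5.0]
        assert np.allclose(before, 2.0)
        assert np.allclose(after, 1.0)  # only the low-bias survivor left

    def test_constant_traces_give_constant_average(self):
        t = np.linspace(0.0, 4.0, 9)
        traces = [BiasTrace(times=t, values=np.full_like(t, 2.5))] * 4
        s = survivor_max_bias(traces, [10.0] * 4)
        assert np.allclose(s.values, 2.5)

    def test_running_max_is_monotone(self, rng):
        t = np.linspace(0.0, 5.0, 50)
        traces = [
            BiasTrace(times=t, values=np.abs(rng.normal(size=50)))
            for _ in range(5)
        ]
        s = survivor_max_bias(traces, [6.0] * 5)
        assert np.all(np.diff(s.values) >= -1e-12)

    def test_zero_runs_rejected(self):
        with pytest.raises(ValueError):
            survivor_max_bias([], [])
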