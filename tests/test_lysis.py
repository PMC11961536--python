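"""Detection statistic: δD spread, normalization, derivatives, calls."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from qcmdlysis import (
    SimParams,
    SpreadSeries,
    classify_lysis,
    delta_d_spread,
    drop_fraction,
    group_compare,
    normalize_spread,
    readout_at,
    second_derivative,
    simulate_experiment,
)
from qcmdlysis.lysis import DegenerateBaselineError
from qcmdlysis.simulate import default_schedule
from qcmdlysis.traces import OvertoneAbsentError


def _series(t, v, normalized=False, t_ref=None):
    return SpreadSeries(np.asarray(t, float), np.asarray(v, float), normalized, t_ref)


class TestDeltaDSpread:
    def test_pointwise_difference(self, control_exp_nf):
        s = delta_d_spread(control_exp_nf)
        expected = control_exp_nf.traces[3].delta_D - control_exp_nf.traces[11].delta_D
        np.testing.assert_array_equal(s.value, expected)

    def test_equal_overtones_give_zero(self, control_exp_nf):
        exp = control_exp_nf
        import copy

        clone = copy.deepcopy(exp)
        clone.traces[11].delta_D = clone.traces[3].delta_D.copy()
        assert np.all(delta_d_spread(clone).value == 0.0)

    def test_missing_overtone_rejected(self, control_exp_nf):
        import copy

        clone = copy.deepcopy(control_exp_nf)
        traces = dict(clone.traces)
        del traces[11]
        clone.traces = traces
        with pytest.raises(OvertoneAbsentError):
            delta_d_spread(clone)

    def test_grows_with_film_during_growth(self, control_exp_nf):
        """Noise-free growth: δD strictly increases while the film thickens."""
        s = delta_d_spread(control_exp_nf)
        ph = control_exp_nf.schedule.phase("growth_static")
        m = (s.time >= ph.start + 1) & (s.time < ph.end)
        assert np.all(np.diff(s.value[m]) > 0)


class TestNormalizeSpread:
    def test_pre_window_maximum_is_one(self, control_exp_nf):
        norm = normalize_spread(delta_d_spread(control_exp_nf), 185.0)
        assert np.max(norm.value[norm.time < 185.0]) == pytest.approx(1.0)
        assert norm.normalized and norm.t_ref == 185.0

    def test_scale_invariance(self):
        t = np.arange(10.0)
        base = _series(t, t + 1.0)
        scaled = _series(t, 3.7 * (t + 1.0))
        a = normalize_spread(base, 5.0)
        b = normalize_spread(scaled, 5.0)
        np.testing.assert_allclose(a.value, b.value, rtol=1e-12)

    def test_idempotence(self):
        t = np.arange(10.0)
        once = normalize_spread(_series(t, t + 1.0), 5.0)
        twice = normalize_spread(once, 5.0)
        np.testing.assert_allclose(once.value, twice.value, rtol=1e-12)

    def test_degenerate_baseline_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(DegenerateBaselineError):
            normalize_spread(_series(t, np.zeros(10)), 5.0)

    def test_requires_pre_window_samples(self):
        t = np.arange(10.0, 20.0)
        with pytest.raises(ValueError, match="no samples"):
            normalize_spread(_series(t, t), 5.0)


class TestSecondDerivative:
    def test_quadratic_is_exact(self):
        t = np.arange(0.0, 50.0, 0.5)
        a, b, c = 0.37, -1.4, 2.0
        series = _series(t, a * t**2 + b * t + c)
        d2 = second_derivative(series, (5.0, 45.0), smoothing_halfwidth=4)
        np.testing.assert_allclose(d2.value, 2.0 * a, rtol=1e-9)

    def test_linear_is_zero(self):
        t = np.arange(0.0, 30.0, 0.5)
        d2 = second_derivative(_series(t, 3.0 * t - 7.0), (2.0, 28.0), 3)
        np.testing.assert_allclose(d2.value, 0.0, atol=1e-12)

    def test_sine_matches_analytic_as_grid_refines(self):
        """Central differences converge to −ω² sin(ωt) with vanishing error."""
        omega = 0.5
        errs = []
        for dt in (0.2, 0.1, 0.05):
            t = np.arange(0.0, 40.0, dt)
            d2 = second_derivative(_series(t, np.sin(omega * t)), (5.0, 35.0), 0)
            exact = -(omega**2) * np.sin(omega * d2.time)
            errs.append(np.max(np.abs(d2.value - exact)[1:-1]))
        assert errs[0] < 1e-3
        assert errs[2] < errs[1] < errs[0]

    def test_too_few_samples_rejected(self):
        t = np.arange(0.0, 3.0, 0.5)
        with pytest.raises(ValueError, match="samples"):
            second_derivative(_series(t, t), (0.0, 1.5), 0)

    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValueError, match="uniform"):
            second_derivative(_series(t, t), (0.0, 6.0), 0)


class TestClassifyLysis:
    def test_constant_series_ties_to_non_lytic(self):
        sched = default_schedule()
        t = np.arange(0.0, 400.0, 0.5)
        norm = _series(t, np.ones_like(t), normalized=True, t_ref=185.0)
        call = classify_lysis(norm, sched)
        assert call.derivative_mean == 0.0
        assert call.label == "non_lytic"

    def test_requires_normalized_series(self):
        sched = default_schedule()
        t = np.arange(0.0, 400.0, 0.5)
        with pytest.raises(ValueError, match="normalized"):
            classify_lysis(_series(t, t), sched)

    def test_unknown_rule_rejected(self):
        sched = default_schedule()
        t = np.arange(0.0, 400.0, 0.5)
        norm = _series(t, np.ones_like(t), normalized=True)
        with pytest.raises(ValueError, match="rule"):
            classify_lysis(norm, sched, rule="median_sign")

    @pytest.mark.parametrize("rule", ["mean_sign", "sum_sign"])
    def test_noise_free_scenarios_classified_correctly(self, rule):
        for params, expected in (
            (SimParams.infectious(titer=8e7, noise_sd_f=0, noise_sd_D=0), "lytic"),
            (SimParams.infectious(titer=4e5, noise_sd_f=0, noise_sd_D=0), "lytic"),
            (SimParams.control(noise_sd_f=0, noise_sd_D=0), "non_lytic"),
            (SimParams.non_infectious(noise_sd_f=0, noise_sd_D=0), "non_lytic"),
        ):
            exp = simulate_experiment(params)
            norm = normalize_spread(delta_d_spread(exp), 185.0)
            call = classify_lysis(norm, exp.schedule, rule=rule)
            assert call.label == expected, params.scenario


class TestDropFraction:
    def test_constant_series_has_zero_drop(self):
        sched = default_schedule()
        t = np.arange(0.0, 400.0, 0.5)
        norm = _series(t, np.ones_like(t), normalized=True, t_ref=185.0)
        assert drop_fraction(norm, sched) == pytest.approx(0.0)

    def test_eighty_percent_drop(self):
        """Unity before injection falling to 0.2 afterwards reads as 0.8."""
        sched = default_schedule()
        t = np.arange(0.0, 400.0, 0.5)
        v = np.where(t < 200.0, 1.0, 0.2)
        norm = _series(t, v, normalized=True, t_ref=185.0)
        assert drop_fraction(norm, sched) == pytest.approx(0.8)

    def test_rising_signal_gives_negative_drop(self):
        sched = default_schedule()
        t = np.arange(0.0, 400.0, 0.5)
        v = np.where(t <= 185.0, 1.0, 1.2)
        norm = _series(t, v, normalized=True, t_ref=185.0)
        assert drop_fraction(norm, sched) == pytest.approx(-0.2)


class TestReadout:
    def test_grid_point_is_exact(self):
        t = np.arange(0.0, 10.0, 0.5)
        s = _series(t, t**2)
        assert readout_at(s, 3.0) == 9.0

    def test_midpoint_interpolates(self):
        s = _series([0.0, 1.0], [0.2, 0.4])
        assert readout_at(s, 0.5) == pytest.approx(0.3)

    def test_outside_span_rejected(self):
        s = _series([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="outside"):
            readout_at(s, 2.0)


def _welch_oracle(a, b):
    """Brute-force Welch t-test from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return t, dof, p


class TestGroupCompare:
    def test_identical_groups_are_ns(self):
        res = group_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_matches_brute_force_welch(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.9, 0.05, 6)
        b = rng.normal(0.2, 0.08, 5)
        res = group_compare(a, b)
        t, dof, p = _welch_oracle(a, b)
        assert res.t_statistic == pytest.approx(t, rel=1e-10)
        assert res.degrees_of_freedom == pytest.approx(dof, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_large_shift_is_three_stars(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        res = group_compare(a, b)
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            group_compare([1.0], [1.0, 2.0])
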