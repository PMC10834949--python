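"""Two-phase SPR kinetic model evaluation and global fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilbind.spr import (
    Sensorgram,
    TwoPhaseKineticParams,
    compute_kd,
    eval_association,
    eval_dissociation,
    eval_sensorgram,
    global_fit,
    subtract_reference,
)
from fibrilbind.synthetic import SyntheticConfig, gen_sensorgram_series


def make_params(**kw):
    base = dict(
        k_on1=1e5, k_on2=1e3, k_off1=1e-3, k_off2=1e-2,
        B_max1=100.0, B_max2=50.0, a=0.5, t_0=300.0,
    )
    base.update(kw)
    return TwoPhaseKineticParams(**base)


class TestEvalAssociation:
    def test_zero_at_t0(self):
        assert eval_association(make_params(), 1e-6, 0.0) == 0.0

    def test_single_phase_plateau(self):
        # B_max2 = 0 annihilates the second term; plateau is the first
        # term's saturating coefficient
        p = make_params(B_max2=0.0)
        c = 1e-6
        plateau = p.k_on1 * c * p.B_max1 / (p.k_on1 * c + p.k_off2)
        assert eval_association(p, c, 1e6) == pytest.approx(plateau, rel=1e-12)

    def test_against_arithmetic_oracle(self):
        # independent hand-coded evaluation of the two-term closed form
        p = make_params()
        c, t = 1e-6, 50.0
        kobs1 = c * 1e5 + 1e-2
        kobs2 = c * 1e3 + 1e-3
        oracle = (
            1e5 * c * 100.0 / kobs1 * (1 - np.exp(-kobs1 * t))
            + 1e3 * c * 50.0 / kobs2 * (1 - np.exp(-kobs2 * t))
        )
        val = eval_association(p, c, t)
        assert val == pytest.approx(oracle, rel=1e-14)
        assert val == pytest.approx(92.91663078196794, rel=1e-12)

    def test_paired_pairing_changes_kobs(self):
        p = make_params()
        c, t = 1e-6, 50.0
        crossed = eval_association(p, c, t, pairing="crossed")
        paired = eval_association(p, c, t, pairing="paired")
        kobs1p = c * p.k_on1 + p.k_off1
        kobs2p = c * p.k_on2 + p.k_off2
        oracle = (
            p.k_on1 * c * p.B_max1 / kobs1p * (1 - np.exp(-kobs1p * t))
            + p.k_on2 * c * p.B_max2 / kobs2p * (1 - np.exp(-kobs2p * t))
        )
        assert paired == pytest.approx(oracle, rel=1e-14)
        assert paired != pytest.approx(crossed, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            eval_association(make_params(), 1e-6, -1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(c=st.floats(1e-9, 1e-3))
    def test_monotone_nondecreasing_in_time(self, c):
        t = np.linspace(0, 2000, 400)
        r = eval_association(make_params(), c, t)
        assert np.all(np.diff(r) >= -1e-12)

    def test_plateau_limit_high_concentration(self):
        # association plateau approaches B_max1 + B_max2 as c -> infinity
        p = make_params()
        val = eval_association(p, 1.0, 1e7)
        assert val == pytest.approx(p.B_max1 + p.B_max2, rel=1e-4)


class TestEvalDissociation:
    def test_equals_r0_at_t0(self):
        p = make_params(R_0=80.0)
        assert eval_dissociation(p, 300.0) == pytest.approx(80.0)

    def test_pure_single_exponential_when_a_is_one(self):
        p = make_params(a=1.0, R_0=50.0)
        t = np.array([300.0, 400.0, 700.0])
        expect = 50.0 * np.exp(-p.k_off1 * (t - 300.0))
        np.testing.assert_allclose(eval_dissociation(p, t), expect, rtol=1e-14)

    def test_equal_offrates_independent_of_a(self):
        t = np.linspace(300, 900, 50)
        r1 = eval_dissociation(make_params(k_off1=5e-3, k_off2=5e-3, a=0.2, R_0=60.0), t)
        r2 = eval_dissociation(make_params(k_off1=5e-3, k_off2=5e-3, a=0.9, R_0=60.0), t)
        np.testing.assert_allclose(r1, r2, rtol=1e-14)

    def test_before_t0_rejected(self):
        with pytest.raises(ValueError):
            eval_dissociation(make_params(R_0=10.0), 299.0)


class TestSubtractReference:
    def _sg(self, responses, times=None):
        times = np.arange(10.0) if times is None else times
        return Sensorgram(1e-6, times, responses, t_0=5.0)

    def test_identical_blank_gives_zero(self):
        s = self._sg(np.arange(10.0) + 1)
        out = subtract_reference(s, s)
        assert np.all(out.responses == 0)
        assert out.reference_subtracted

    def test_zero_blank_is_identity(self):
        s = self._sg(np.arange(10.0) + 1)
        out = subtract_reference(s, self._sg(np.zeros(10)))
        np.testing.assert_array_equal(out.responses, s.responses)

    def test_linear_drift_removed(self):
        t = np.arange(10.0)
        signal = np.sin(t)
        drift = 0.3 * t + 2.0
        out = subtract_reference(self._sg(signal + drift + 5.0), self._sg(drift + 5.0))
        np.testing.assert_allclose(out.responses, signal, atol=1e-12)

    def test_mismatched_grids_require_interpolation(self):
        s = self._sg(np.arange(10.0))
        b = Sensorgram(1e-6, np.arange(10.0) + 0.5, np.zeros(10), t_0=5.5)
        with pytest.raises(ValueError):
            subtract_reference(s, b)
        out = subtract_reference(s, b, interpolate=True)
        assert out.responses.shape == s.responses.shape


class TestComputeKd:
    def test_direct_division(self):
        p = make_params(k_on1=1e5, k_off2=1e-3)
        kd_strong, _ = compute_kd(p, "crossed")
        assert kd_strong == pytest.approx(1e-8)

    def test_symmetric_rates_collapse(self):
        p = make_params(k_on1=1e4, k_on2=1e4, k_off1=1e-3, k_off2=1e-3)
        s, w = compute_kd(p)
        assert s == w

    def test_label_swap_preserves_value_set(self):
        p = make_params()
        swapped = make_params(
            k_on1=p.k_on2, k_on2=p.k_on1, k_off1=p.k_off2, k_off2=p.k_off1
        )
        assert sorted(compute_kd(p)) == pytest.approx(sorted(compute_kd(swapped)))


class TestGlobalFit:
    def test_noiseless_identity(self, demo_kinetics, conc_series, t_grid):
        series = gen_sensorgram_series(
            demo_kinetics, conc_series, t_grid, SyntheticConfig(rng_seed=0)
        )
        fit = global_fit(series, exclude_lowest=2, n_starts=4, seed=0)
        assert fit.converged
        for name in ("k_on1", "k_on2", "k_off1", "k_off2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(demo_kinetics, name), rel=1e-4
            )
        assert fit.kd_strong == pytest.approx(1.29e-8, rel=1e-4)

    def test_paired_pairing_roundtrip(self, demo_kinetics, conc_series, t_grid):
        series = gen_sensorgram_series(
            demo_kinetics, conc_series, t_grid, SyntheticConfig(rng_seed=0),
            pairing="paired",
        )
        fit = global_fit(series, exclude_lowest=2, pairing="paired", n_starts=4, seed=0)
        assert fit.converged
        for name in ("k_on1", "k_on2", "k_off1", "k_off2"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(demo_kinetics, name), rel=1e-3
            )

    def test_exclusion_bookkeeping(self, demo_kinetics, conc_series, t_grid):
        series = gen_sensorgram_series(
            demo_kinetics, conc_series, t_grid, SyntheticConfig(rng_seed=0)
        )
        fit = global_fit(series, exclude_lowest=2, n_starts=2, seed=0)
        assert fit.excluded_concentrations == sorted(conc_series)[:2]
        # exactly 7 of the 9 concentrations enter the objective
        assert len(fit.r0_per_curve) == 7

    def test_response_unit_rescaling_invariance(self, demo_kinetics, conc_series, t_grid):
        cfg = SyntheticConfig(rng_seed=4, noise_sd_sensorgram=0.5)
        series = gen_sensorgram_series(demo_kinetics, conc_series, t_grid, cfg)
        fit1 = global_fit(series, exclude_lowest=2, n_starts=4, seed=1)
        scaled = [
            Sensorgram(s.concentration, s.times, 10.0 * s.responses, s.t_0,
                       s.reference_subtracted, s.curve_id)
            for s in series
        ]
        fit2 = global_fit(scaled, exclude_lowest=2, n_starts=4, seed=1)
        for name in ("k_on1", "k_on2", "k_off1", "k_off2"):
            assert getattr(fit2.params, name) == pytest.approx(
                getattr(fit1.params, name), rel=1e-3
            )
        assert fit2.params.B_max1 == pytest.approx(10 * fit1.params.B_max1, rel=1e-3)

    def test_too_few_concentrations_rejected(self, demo_kinetics, t_grid):
        series = gen_sensorgram_series(
            demo_kinetics, [1e-6, 2e-6, 4e-6], t_grid, SyntheticConfig(rng_seed=0)
        )
        with pytest.raises(ValueError):
            global_fit(series, exclude_lowest=2)


class TestSensorgramContinuity:
    def test_continuous_at_injection_stop(self, demo_kinetics):
        t = np.linspace(0, 900, 1801)
        for c in (1e-7, 1e-6, 1e-5):
            asso_end = eval_association(demo_kinetics, c, demo_kinetics.t_0)
            trace = eval_sensorgram(demo_kinetics, c, t, demo_kinetics.t_0)
            idx = np.searchsorted(t, demo_kinetics.t_0)
            assert trace[idx] == pytest.approx(asso_end, rel=1e-12)
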