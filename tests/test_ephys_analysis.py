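"""Sweep-analysis procedures: Rin, tau fits, PSP amplitudes, failures, swim peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixedsyn import ephys_analysis as ea
from mixedsyn.exceptions import (
    CannotIsolateError,
    InsufficientDataError,
    WindowTruncationError,
)
from mixedsyn.sweeps import SweepSet


def _step_sweeps(n=3, rin_mohm=1000.0, current=-5.0, noise=0.0, seed=0, tau=3.0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 110.0, 0.05)
    v = np.full_like(t, -60.0)
    dv = current * rin_mohm * 1e-3
    on = (t >= 20.0) & (t < 70.0)
    v[on] += dv * (1 - np.exp(-(t[on] - 20.0) / tau))
    off = t >= 70.0
    v[off] += dv * np.exp(-(t[off] - 70.0) / tau)
    data = v[None, :] + rng.normal(0, noise, (n, t.size))
    return SweepSet(time=t, data=data, stim_onset=20.0, stim_duration=50.0,
                    stim_amplitude=current)


class TestInputResistance:
    def test_ohms_law_on_noiseless_sweeps(self):
        sw = _step_sweeps(3, rin_mohm=1000.0)
        assert ea.input_resistance(sw) == pytest.approx(1000.0, rel=1e-3)

    def test_recovery_under_noise(self):
        sw = _step_sweeps(5, rin_mohm=500.0, noise=0.2, seed=1)
        assert ea.input_resistance(sw) == pytest.approx(500.0, rel=0.05)

    def test_fewer_than_three_sweeps_rejected(self):
        sw = _step_sweeps(3).subset([0, 1])
        with pytest.raises(InsufficientDataError):
            ea.input_resistance(sw)

    def test_zero_current_rejected(self):
        sw = _step_sweeps(3)
        with pytest.raises(ValueError):
            ea.input_resistance(sw, injected_current=0.0)


class TestDoubleExponentialFit:
    def test_single_exponential_limit(self):
        t = np.arange(0.0, 30.0, 0.05)
        y = 5.0 * np.exp(-t / 3.0)
        fit = ea.fit_double_exponential(t, y)
        assert fit.weighted_tau == pytest.approx(3.0, rel=0.02)

    def test_two_component_recovery_with_noise(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 60.0, 0.05)
        y = 3.0 * np.exp(-t / 2.0) + 1.0 * np.exp(-t / 10.0)
        y += rng.normal(0, 0.05, t.size)
        fit = ea.fit_double_exponential(t, y)
        # weighted tau = 0.75*2 + 0.25*10 = 4.0
        assert fit.weighted_tau == pytest.approx(4.0, rel=0.05)
        assert fit.tau1 <= fit.tau2

    def test_equal_amplitudes_average_the_time_constants(self):
        t = np.arange(0.0, 80.0, 0.05)
        y = 2.0 * np.exp(-t / 2.0) + 2.0 * np.exp(-t / 10.0)
        fit = ea.fit_double_exponential(t, y)
        assert fit.weighted_tau == pytest.approx(6.0, rel=0.02)

    def test_weighted_tau_is_convex_combination(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rng.uniform(0.5, 5, 2)
            t1, t2 = sorted(rng.uniform(1, 20, 2))
            t = np.arange(0.0, 100.0, 0.1)
            fit = ea.fit_double_exponential(t, a * np.exp(-t / t1) + b * np.exp(-t / t2))
            assert fit.tau1 - 1e-9 <= fit.weighted_tau <= fit.tau2 + 1e-9

    def test_negative_going_relaxation_supported(self):
        t = np.arange(0.0, 30.0, 0.05)
        fit = ea.fit_double_exponential(t, -4.0 * np.exp(-t / 3.0))
        assert fit.weighted_tau == pytest.approx(3.0, rel=0.02)
        assert fit.a + fit.b == pytest.approx(-4.0, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            ea.fit_double_exponential(np.arange(10.0), np.exp(-np.arange(10.0)))


class TestPSPAmplitude:
    def _psp(self, amp=6.0, base=-60.0, rise=0.5, decay=3.0):
        t = np.arange(0.0, 30.0, 0.05)
        v = np.full_like(t, base)
        s = np.clip(t - 10.0, 0, None)
        tp = rise * decay / (decay - rise) * np.log(decay / rise)
        norm = np.exp(-tp / decay) - np.exp(-tp / rise)
        v += amp * (np.exp(-s / decay) - np.exp(-s / rise)) / norm
        v[t < 10.0] = base
        return t, v

    def test_flat_baseline(self):
        t, v = self._psp(6.0)
        assert ea.psp_amplitude(t, v, 10.0) == pytest.approx(6.0, rel=0.01)

    @settings(deadline=None, max_examples=20)
    @given(offset=st.floats(-30.0, 30.0))
    def test_offset_invariance(self, offset):
        t, v = self._psp(4.0)
        a0 = ea.psp_amplitude(t, v, 10.0)
        assert ea.psp_amplitude(t, v + offset, 10.0) == pytest.approx(a0, abs=1e-9)

    def test_missing_baseline_window_rejected(self):
        t = np.arange(0.0, 5.0, 0.05)
        with pytest.raises(InsufficientDataError):
            ea.psp_amplitude(t, np.zeros_like(t), 0.5)


class TestFailuresAndIsolation:
    @staticmethod
    def _kernel(s, latency, rise, decay):
        u = s - latency
        tp = rise * decay / (decay - rise) * np.log(decay / rise)
        norm = np.exp(-tp / decay) - np.exp(-tp / rise)
        return np.where(u > 0, np.exp(-u / decay) - np.exp(-u / rise), 0.0) / norm

    def _mixed(self, n=100, n_fail=20, elec=1.5, chem=2.0, noise=0.1, seed=0):
        # fast reliable electrical component, slower chemical component in
        # the 1.5-8 ms detection window
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 30.0, 0.05)
        s = np.clip(t - 10.0, 0, None)
        ek = elec * self._kernel(s, 0.2, 0.15, 0.5)
        ck = chem * self._kernel(s, 2.5, 0.5, 3.0)
        fails = np.zeros(n, dtype=bool)
        fails[:n_fail] = True
        data = np.full((n, t.size), -60.0) + ek[None, :]
        data[~fails] += ck[None, :]
        data += rng.normal(0, noise, data.shape)
        return SweepSet(time=t, data=data, spike_time=10.0,
                        meta={"true_failures": fails})

    def test_programmed_failure_rate_recovered(self):
        sw = self._mixed(100, 20)
        flags, rate = ea.classify_failures(sw)
        assert rate == pytest.approx(20.0)
        assert np.array_equal(flags, sw.meta["true_failures"])

    def test_no_failures_gives_zero_rate(self):
        sw = self._mixed(50, 0)
        _, rate = ea.classify_failures(sw)
        assert rate == 0.0

    def test_sweep_count_outside_recommendation_warns(self):
        sw = self._mixed(8, 2)
        with pytest.warns(UserWarning):
            ea.classify_failures(sw)

    def test_template_subtraction_recovers_chemical_amplitude(self):
        sw = self._mixed(80, 20, elec=1.5, chem=2.0)
        flags, _ = ea.classify_failures(sw)
        chem = ea.isolate_chemical_component(sw, flags)
        amp = ea.psp_amplitude(chem.time, chem.data[~flags].mean(axis=0), 10.0)
        assert amp == pytest.approx(2.0, rel=0.05)

    def test_all_failures_leave_noise_only_chemical(self):
        sw = self._mixed(30, 30)
        flags, rate = ea.classify_failures(sw)
        assert rate == 100.0
        chem = ea.isolate_chemical_component(sw, flags)
        # the template is the grand mean, so the residual averages to zero
        # and individual sweeps carry nothing but noise
        assert np.allclose(chem.data.mean(axis=0), 0.0, atol=1e-9)
        assert np.abs(chem.data).max() < 6 * 0.1

    def test_isolation_without_failures_is_undefined(self):
        sw = self._mixed(30, 0)
        with pytest.raises(CannotIsolateError):
            ea.isolate_chemical_component(sw, np.zeros(30, dtype=bool))

    def test_adding_template_back_reconstructs_sweeps_exactly(self):
        sw = self._mixed(40, 10)
        flags, _ = ea.classify_failures(sw)
        chem = ea.isolate_chemical_component(sw, flags)
        rebuilt = chem.data + chem.meta["electrical_template"][None, :]
        assert np.array_equal(rebuilt, sw.data)


class TestDecayTau:
    def test_pure_exponential(self):
        t = np.arange(0.0, 30.0, 0.02)
        v = 3.0 * np.exp(-t / 3.0)
        assert ea.psp_decay_tau(t, v) == pytest.approx(3.0, rel=0.05)

    def test_fast_component_reported_from_mixture(self):
        t = np.arange(0.0, 80.0, 0.02)
        v = 2.0 * np.exp(-t / 2.0) + 1.0 * np.exp(-t / 15.0)
        assert ea.psp_decay_tau(t, v) == pytest.approx(2.0, rel=0.25)

    def test_truncated_decay_rejected(self):
        t = np.arange(0.0, 3.0, 0.02)
        v = 3.0 * np.exp(-t / 30.0)  # barely decays within the record
        with pytest.raises(WindowTruncationError):
            ea.psp_decay_tau(t, v)


class TestScalarConversions:
    @pytest.mark.parametrize(
        "amp, rin, expected", [(5.0, 50.0, 100.0), (0.0, 700.0, 0.0), (2.0, 1000.0, 2.0)]
    )
    def test_ohmic_current(self, amp, rin, expected):
        assert ea.ohmic_current(amp, rin) == pytest.approx(expected)

    def test_ohmic_current_rejects_nonpositive_rin(self):
        with pytest.raises(ValueError):
            ea.ohmic_current(1.0, 0.0)

    @pytest.mark.parametrize(
        "pre, post, expected", [(500.0, 750.0, 150.0), (400.0, 400.0, 100.0), (400.0, 300.0, 75.0)]
    )
    def test_percent_control(self, pre, post, expected):
        assert ea.percent_control(pre, post) == pytest.approx(expected)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 10.0))
    def test_ohmic_current_scales_linearly(self, scale):
        base = ea.ohmic_current(2.0, 100.0)
        assert ea.ohmic_current(2.0 * scale, 100.0) == pytest.approx(base * scale)
        assert ea.ohmic_current(2.0, 100.0 * scale) == pytest.approx(base / scale)


class TestSwimCurrents:
    def test_programmed_peaks_recovered(self):
        t = np.arange(0.0, 1000.0, 0.1)
        i = np.zeros_like(t)
        bouts = []
        for k, peak in enumerate([100, 110, 120, 130, 140]):
            start = 100.0 + k * 150.0
            m = (t >= start) & (t < start + 100.0)
            i[m] = -peak * np.sin(np.pi * (t[m] - start) / 100.0)
            bouts.append((start, start + 100.0))
        res = ea.peak_swim_current(t, i, bouts)
        assert np.allclose(res.peaks, [100, 110, 120, 130, 140], rtol=1e-3)
        assert res.mean == pytest.approx(120.0, rel=1e-3)

    def test_flat_trace_gives_zero(self):
        t = np.arange(0.0, 500.0, 0.1)
        res = ea.peak_swim_current(t, np.zeros_like(t), [(100.0, 200.0)] * 5)
        assert np.all(res.peaks == 0.0)

    def test_fewer_than_five_bouts_warns(self):
        t = np.arange(0.0, 500.0, 0.1)
        with pytest.warns(UserWarning):
            ea.peak_swim_current(t, np.zeros_like(t), [(100.0, 200.0)] * 3)

    def test_no_bouts_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(InsufficientDataError):
            ea.peak_swim_current(t, np.zeros_like(t), [])
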