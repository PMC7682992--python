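"""Signal-feature unit and property tests: filtering, analytic signal,
power, WPLI, amplitude covariation, phase-amplitude coupling, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetalink import features as F

from conftest import ALPHA, FS, HIGH_GAMMA, THETA, theta_noise


def tone(f, duration=20.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * f * t)


class TestBandpass:
    def test_passband_identity(self):
        y = F.bandpass(tone(8.0), THETA, FS)
        core = y[10000:-10000]
        assert np.abs(core).max() >= 0.95

    def test_stopband_rejection(self):
        y = F.bandpass(tone(50.0), THETA, FS)
        assert np.abs(y[10000:-10000]).max() <= 0.05

    def test_dc_rejected(self):
        y = F.bandpass(np.ones(40000), THETA, FS)
        assert np.abs(y[5000:-5000]).max() < 1e-6

    def test_filter_length_is_three_periods_of_low_edge(self):
        n = F.fir_length(THETA, FS)
        assert abs(n - 3 * FS / THETA.lo) <= 1

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            F.bandpass(np.zeros(100), THETA, FS)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            F.bandpass(tone(8.0), F.BandSpec("bad", 500.0, 1500.0), FS)


class TestAnalytic:
    def test_cosine_amplitude_and_phase_rate(self):
        x = np.cos(2 * np.pi * 8.0 * np.arange(int(10 * FS)) / FS)
        a = F.analytic(x, FS)
        core = slice(2000, -2000)
        assert np.allclose(a.amplitude[core], 1.0, atol=1e-3)
        dphi = np.diff(np.unwrap(a.phase))[core]
        assert np.allclose(dphi, 2 * np.pi * 8.0 / FS, atol=1e-4)

    def test_am_envelope_recovered(self):
        t = np.arange(int(20 * FS)) / FS
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        a = F.analytic(env * np.cos(2 * np.pi * 8.0 * t), FS)
        core = slice(4000, -4000)
        assert np.abs(a.amplitude[core] - env[core]).max() < 0.05

    def test_zero_signal(self):
        a = F.analytic(np.zeros(1000), FS)
        assert np.all(a.amplitude == 0)
        assert np.all(np.isfinite(a.phase))


class TestBandPower:
    def test_unit_sinusoid_recovers_tone_variance(self):
        p = F.band_power(tone(8.0, 60.0), THETA, FS)
        assert abs(p - 0.5) < 0.025

    def test_white_noise_band_share(self):
        x = np.random.default_rng(0).standard_normal(int(120 * FS))
        share = F.band_power(x, THETA, FS) / x.var()
        expected = (THETA.hi - THETA.lo) / (FS / 2)
        assert abs(share - expected) < 0.2 * expected

    def test_zero_signal(self):
        assert F.band_power(np.zeros(int(4 * FS)), THETA, FS) == 0.0

    def test_segment_longer_than_signal(self):
        with pytest.raises(ValueError):
            F.band_power(np.zeros(100), THETA, FS, segment_length=2.0)


class TestWPLI:
    def test_quarter_cycle_lag_saturates(self):
        phase, x = theta_noise(60.0, seed=1)
        y = np.cos(phase - np.pi / 2)
        assert F.wpli(x, y, THETA, FS) >= 0.95

    def test_independent_channels_near_zero(self):
        g = np.random.default_rng(2)
        x = F.bandpass(g.standard_normal(int(120 * FS)), THETA, FS)
        y = F.bandpass(g.standard_normal(int(120 * FS)), THETA, FS)
        assert F.wpli(x, y, THETA, FS) <= 0.1

    def test_zero_lag_returns_zero_by_convention(self):
        _, x = theta_noise(30.0, seed=3)
        assert F.wpli(x, x, THETA, FS) == 0.0

    def test_bounds_and_symmetry_and_scale_invariance(self):
        phase, x = theta_noise(30.0, seed=4)
        y = np.cos(phase - 0.9) + 0.2 * np.random.default_rng(5).standard_normal(x.size)
        v = F.wpli(x, y, THETA, FS)
        assert 0.0 <= v <= 1.0
        assert F.wpli(y, x, THETA, FS) == pytest.approx(v, abs=1e-12)
        assert F.wpli(3.7 * x, 0.2 * y, THETA, FS) == pytest.approx(v, rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            F.wpli(np.zeros(9000), np.zeros(8000), THETA, FS)


class TestLeadLag:
    def test_delay_conventions(self):
        phase, x = theta_noise(30.0, seed=6)
        lagged = np.cos(phase - 0.8)
        assert F.lead_lag_sign(x, lagged, THETA, FS) == "x_leads"
        assert F.lead_lag_sign(lagged, x, THETA, FS) == "y_leads"
        assert F.lead_lag_sign(x, x, THETA, FS) == "indeterminate"


class TestAmplitudeCovariation:
    def test_shared_envelope(self):
        t = np.arange(int(60 * FS)) / FS
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        _, c1 = theta_noise(60.0, seed=7, drift_sd=1.0)
        _, c2 = theta_noise(60.0, seed=8, drift_sd=1.0)
        assert F.amplitude_covariation(env * c1, env * c2, THETA, FS) >= 0.9

    def test_independent_envelopes(self):
        t = np.arange(int(120 * FS)) / FS
        g = np.random.default_rng(9)
        e1 = 1.0 + 0.5 * np.sin(2 * np.pi * 0.21 * t)
        e2 = 1.0 + 0.5 * np.sin(2 * np.pi * 0.29 * t + 2.0)
        _, c1 = theta_noise(120.0, seed=10)
        _, c2 = theta_noise(120.0, seed=11)
        assert abs(F.amplitude_covariation(e1 * c1, e2 * c2, THETA, FS)) <= 0.25

    def test_antiphase_envelopes(self):
        t = np.arange(int(60 * FS)) / FS
        e = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        _, c1 = theta_noise(60.0, seed=12, drift_sd=1.0)
        _, c2 = theta_noise(60.0, seed=13, drift_sd=1.0)
        assert F.amplitude_covariation((1 + e) * c1, (1 - e) * c2, THETA, FS) <= -0.9


class TestCFC:
    def test_am_depth_gives_half_m(self):
        # numerical oracle: |int (1+m cos p) e^{ip} dp| / int (1+m cos p) dp = m/2
        m = 0.6
        p = np.linspace(-np.pi, np.pi, 20001)
        a = 1 + m * np.cos(p)
        oracle = np.abs(np.trapezoid(a * np.exp(1j * p), p)) / np.trapezoid(a, p)
        assert oracle == pytest.approx(m / 2, abs=1e-6)
        t = np.arange(int(120 * FS)) / FS
        phase_low = 2 * np.pi * 4.0 * t
        amp_src = (1 + m * np.cos(phase_low)) * np.cos(2 * np.pi * 80.0 * t)
        mi = F.cfc(np.cos(phase_low), F.BandSpec("Theta", 2, 6), amp_src,
                   HIGH_GAMMA, FS)
        assert abs(mi - m / 2) < 0.02

    def test_constant_amplitude_cancels(self):
        t = np.arange(int(60 * FS)) / FS
        mi = F.cfc(np.cos(2 * np.pi * 4.0 * t), F.BandSpec("Theta", 2, 6),
                   np.cos(2 * np.pi * 80.0 * t), HIGH_GAMMA, FS)
        assert mi < 0.03

    def test_single_phase_concentration_gives_one(self):
        phase = np.full(1000, 0.3)
        amp = np.ones(1000)
        assert F._mi_from_phase_amp(phase, amp) == pytest.approx(1.0)

    def test_monotone_in_depth(self):
        t = np.arange(int(60 * FS)) / FS
        phase_low = 2 * np.pi * 4.0 * t
        mis = []
        for m in (0.2, 0.5, 0.8):
            amp_src = (1 + m * np.cos(phase_low)) * np.cos(2 * np.pi * 80.0 * t)
            mis.append(F.cfc(np.cos(phase_low), F.BandSpec("Theta", 2, 6),
                             amp_src, HIGH_GAMMA, FS))
        assert mis[0] < mis[1] < mis[2]

    def test_amp_rescale_invariance(self):
        t = np.arange(int(30 * FS)) / FS
        phase_low = 2 * np.pi * 4.0 * t
        amp_src = (1 + 0.5 * np.cos(phase_low)) * np.cos(2 * np.pi * 80.0 * t)
        lo = F.BandSpec("Theta", 2, 6)
        v1 = F.cfc(np.cos(phase_low), lo, amp_src, HIGH_GAMMA, FS)
        v2 = F.cfc(np.cos(phase_low), lo, 10.0 * amp_src, HIGH_GAMMA, FS)
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestOracleEquivalence:
    """Vectorized estimators match a direct per-sample loop on short data."""

    def test_wpli_matches_loop(self):
        phase, x = theta_noise(4.0, seed=14)
        y = np.cos(phase - 0.7) + 0.3 * np.random.default_rng(15).standard_normal(x.size)
        za = F.band_analytic(x, THETA, FS)
        zb = F.band_analytic(y, THETA, FS)
        num = den = 0.0
        for aa, pa, ab, pb in zip(za.amplitude, za.phase, zb.amplitude, zb.phase):
            im = aa * ab * np.sin(pa - pb)
            num += im
            den += abs(im)
        assert F.wpli(x, y, THETA, FS) == pytest.approx(abs(num) / den, abs=1e-10)

    def test_cfc_matches_loop(self):
        t = np.arange(int(4 * FS)) / FS
        phase_low = 2 * np.pi * 4.0 * t
        amp_src = (1 + 0.5 * np.cos(phase_low)) * np.cos(2 * np.pi * 80.0 * t)
        x = np.cos(phase_low)
        lo = F.BandSpec("Theta", 2, 6)
        zp = F.band_analytic(x, lo, FS)
        za = F.band_analytic(amp_src, HIGH_GAMMA, FS)
        start = max(zp.offset, za.offset)
        stop = x.size - start
        vec = 0j
        tot = 0.0
        for i in range(start, stop):
            a = za.amplitude[i - za.offset]
            vec += a * np.exp(1j * zp.phase[i - zp.offset])
            tot += a
        assert F.cfc(x, lo, amp_src, HIGH_GAMMA, FS) == pytest.approx(
            abs(vec) / tot, abs=1e-10)


class TestWindowing:
    def test_grid_has_eleven_points(self):
        spec = F.DynamicWindowSpec()
        assert spec.offsets.tolist() == [-7.5, -6.0, -4.5, -3.0, -1.5, 0.0,
                                         1.5, 3.0, 4.5, 6.0, 7.5]

    def test_event_grid_shape_and_edge_exclusion(self, caplog):
        from thetalink.session import PairedRecording
        g = np.random.default_rng(16)
        rec = PairedRecording(hpc=g.standard_normal(int(60 * FS)),
                              pfc=g.standard_normal(int(60 * FS)), fs=FS)
        kept, grids = F.windowed_features(rec, [30.0, 2.0])
        assert kept.tolist() == [30.0]
        assert grids.shape == (1, 11, 40)

    def test_no_valid_events_raises(self):
        from thetalink.session import PairedRecording
        g = np.random.default_rng(17)
        rec = PairedRecording(hpc=g.standard_normal(int(30 * FS)),
                              pfc=g.standard_normal(int(30 * FS)), fs=FS)
        with pytest.raises(ValueError):
            F.windowed_features(rec, [1.0])

    def test_stationary_signal_gives_flat_grid(self):
        from thetalink.session import PairedRecording
        g = np.random.default_rng(18)
        rec = PairedRecording(hpc=g.standard_normal(int(60 * FS)),
                              pfc=g.standard_normal(int(60 * FS)), fs=FS)
        _, grids = F.windowed_features(rec, [30.0])
        ipow = F.FEATURE_NAMES.index("pow_hpcTheta")
        vals = grids[0, :, ipow]
        assert vals.std() / vals.mean() < 0.5  # estimator noise only


class TestZScore:
    def test_mean_zero_sd_one(self):
        g = np.random.default_rng(19).standard_normal((5, 11))
        z = F.zscore_event_dynamics(g)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-12)

    def test_constant_run_flagged_zero(self):
        with pytest.warns(UserWarning):
            z = F.zscore_event_dynamics(np.full(11, 3.0))
        assert np.all(z == 0.0)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        g = np.linspace(-1.0, 2.0, 11)
        assert np.allclose(F.zscore_event_dynamics(a * g + b),
                           F.zscore_event_dynamics(g), atol=1e-8)


def test_feature_catalogue_is_forty():
    names = F.FEATURE_NAMES
    assert len(names) == 40
    assert len(set(names)) == 40
    assert sum(n.startswith("pow_") for n in names) == 8
    assert sum(n.startswith("ampcov_") for n in names) == 4
    assert sum(n.startswith("wpli_") for n in names) == 4
    assert sum(n.startswith("cfc_") for n in names) == 24
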