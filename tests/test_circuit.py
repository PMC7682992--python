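"""Feedforward-inhibition model tests: Poisson inputs, integrate-and-fire
dynamics vs a per-step reference loop, calibration, correlations, sweeps."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sstats

from thetalink import circuit as C


class TestPoisson:
    def test_constant_rate_mean_count(self):
        counts = [C.inhomogeneous_poisson(lambda t: np.full_like(t, 50.0),
                                          1.0, 0.1, rng=s).size
                  for s in range(200)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 50.0) < 3 * se + 1e-9

    def test_zero_rate_empty(self):
        assert C.inhomogeneous_poisson(lambda t: np.zeros_like(t), 1.0, 0.1,
                                       rng=0).size == 0

    def test_sinusoidal_phase_profile(self):
        # spikes drawn from r(t) = 50(1 - cos 2 pi 8 t) must follow that
        # profile in theta phase (chi-square GOF on 20 bins)
        spec = C.InputSpec()
        rng = np.random.default_rng(3)
        times = []
        while sum(len(x) for x in times) < 100_000:
            times.append(C.inhomogeneous_poisson(spec.hpc_rate, 1.0, 0.1, rng=rng))
        t = np.concatenate(times)
        phase = (t * 8.0) % 1.0
        obs, edges = np.histogram(phase, bins=20, range=(0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        expected = 1.0 - np.cos(2 * np.pi * centers)
        expected = expected / expected.sum() * obs.sum()
        chi2 = np.sum((obs - expected) ** 2 / expected)
        assert sstats.chi2.sf(chi2, df=19) > 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            C.inhomogeneous_poisson(lambda t: -np.ones_like(t), 1.0, 0.1, rng=0)

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            C.inhomogeneous_poisson(lambda t: np.full_like(t, 5000.0), 1.0, 0.1,
                                    rng=0)


class TestSimulator:
    def test_zero_inputs_zero_spikes(self):
        p = C.CircuitParams(w_hpc_pyr=0.1, w_noise_pyr=0.1,
                            w_hpc_fsin=0.1, w_noise_fsin=0.1, w_fsin_pyr=-0.1)
        n = 10_000
        sim = C.simulate_circuit(p, C.InputSpec(), input_spikes=(
            np.zeros((1, n), bool), np.zeros((1, n), bool)))
        assert sim.pyr.sum() == 0 and sim.fsin.sum() == 0

    def test_refractory_bounds_rate(self):
        # overwhelming drive: rate capped near 1 / refractory period
        p = C.CircuitParams(w_hpc_pyr=50.0, w_noise_pyr=50.0, t_refractory=2.0)
        sim = C.simulate_circuit(p, C.InputSpec(), seed=0, n_iter=20)
        assert sim.rate("pyr") <= 1000.0 / p.t_refractory

    def test_inhibition_monotonically_reduces_pyr_rate(self):
        spec = C.InputSpec()
        rates = []
        for w_inh in (0.0, -0.05, -0.15):
            p = C.CircuitParams(w_hpc_pyr=0.12, w_noise_pyr=0.12,
                                w_hpc_fsin=0.07, w_noise_fsin=0.07,
                                w_fsin_pyr=w_inh)
            rates.append(C.simulate_circuit(p, spec, seed=5, n_iter=100).rate("pyr"))
        assert rates[0] >= rates[1] >= rates[2]

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            C.CircuitParams(dt=5.0)

    def test_positive_inhibitory_weight_rejected(self):
        with pytest.raises(ValueError):
            C.CircuitParams(w_fsin_pyr=0.1)

    def test_batch_matches_reference_loop(self):
        # event-level oracle: vectorized simulator reproduces the naive
        # per-dt scalar loop spike for spike at fine resolution
        p = C.CircuitParams(dt=0.01, w_hpc_pyr=0.12, w_noise_pyr=0.12,
                            w_hpc_fsin=0.07, w_noise_fsin=0.07,
                            w_fsin_pyr=-0.1)
        spec = C.InputSpec()
        rng = np.random.default_rng(7)
        hpc, noise = C._input_spike_matrices(spec, p.dt, 1, rng)
        sim = C.simulate_circuit(p, spec, input_spikes=(hpc, noise))
        ref_pyr, ref_fsin = C.simulate_reference(p, hpc[0], noise[0])
        assert ref_pyr.sum() > 0 and ref_fsin.sum() > 0
        assert np.array_equal(sim.pyr[0], ref_pyr)
        assert np.array_equal(sim.fsin[0], ref_fsin)


class TestBinnedCorrelation:
    def test_identical_trains(self):
        spikes = np.random.default_rng(0).random((5, 10_000)) < 0.005
        assert C.binned_correlation(spikes, spikes, dt=0.1) == pytest.approx(1.0)

    def test_independent_trains_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((1000, 10_000)) < 0.005
        b = rng.random((1000, 10_000)) < 0.005
        ca, cb = C.bin_spikes(a, 0.1), C.bin_spikes(b, 0.1)
        rs = C._batch_corr(ca, cb)
        se = np.nanstd(rs) / np.sqrt(np.sum(~np.isnan(rs)))
        assert abs(np.nanmean(rs)) < 3 * se + 1e-9

    def test_large_jitter_decorrelates(self):
        rng = np.random.default_rng(2)
        n = 100_000  # 10 s at dt 0.1 ms
        a = rng.random(n) < 0.005
        idx = np.flatnonzero(a)
        jit = np.clip(idx + rng.integers(-3000, 3000, idx.size), 0, n - 1)
        b = np.zeros(n, bool)
        b[jit] = True
        r_self = C.binned_correlation(a[None], a[None], dt=0.1)
        r_jit = C.binned_correlation(a[None], b[None], dt=0.1)
        assert r_jit < 0.1 * r_self

    def test_zero_variance_flagged(self):
        a = np.zeros((1, 10_000), bool)
        assert C.binned_correlation(a, a, dt=0.1) == 0.0


class TestCalibration:
    def test_paper_operating_point_feasible(self, calibrated_params):
        rates = C.operating_rates(calibrated_params, C.InputSpec(),
                                  seed=99, n_iter=300)
        assert rates.fsin_rate == pytest.approx(20.0, rel=0.10)
        assert rates.pyr_rate_inhibited == pytest.approx(25.0, rel=0.10)
        assert rates.pyr_rate_uninhibited == pytest.approx(50.0, rel=0.10)

    def test_zero_targets_trivially_feasible(self):
        p = C.calibrate_operating_point(C.OperatingPoint(0.0, 0.0, 0.0))
        assert p.w_hpc_pyr == 0.0 and p.w_fsin_pyr == 0.0

    def test_inverted_targets_rejected(self):
        with pytest.raises(ValueError):
            C.calibrate_operating_point(C.OperatingPoint(20.0, 50.0, 25.0))


class TestSweeps:
    def test_zero_drive_silences_fsin_and_restores_pyr(self, calibrated_params):
        df = C.sweep_fsin_drive(calibrated_params, grid=[0.0], seed=21,
                                n_iter=300)
        assert df.rate_fsin[0] == 0.0
        assert df.rate_pyr[0] == pytest.approx(50.0, rel=0.10)

    def test_fsin_rate_nondecreasing_in_drive(self, calibrated_params):
        df = C.sweep_fsin_drive(calibrated_params, grid=np.linspace(0, 2, 6),
                                seed=22, n_iter=150)
        rates = df.rate_fsin.to_numpy()
        assert np.all(np.diff(rates) >= -1.0)  # Monte-Carlo slack, Hz

    def test_disinhibition_with_zero_isi_weights_reduces_exactly(
            self, calibrated_params):
        grid = [0.5, 1.0]
        a = C.sweep_fsin_drive(calibrated_params, grid=grid, seed=23, n_iter=50)
        b = C.disinhibition_variant(calibrated_params, grid=grid, seed=23,
                                    n_iter=50)
        assert np.allclose(a.rate_pyr, b.rate_pyr)
        assert np.allclose(a.snr, b.snr, equal_nan=True)

    def test_disinhibition_shifts_pyr_curve_right(self, calibrated_params):
        dis = dataclasses.replace(
            calibrated_params,
            w_hpc_isi=calibrated_params.w_hpc_fsin,
            w_noise_isi=calibrated_params.w_noise_fsin,
            w_isi_fsin=-0.08)
        grid = [1.0, 1.5]
        base = C.sweep_fsin_drive(calibrated_params, grid=grid, seed=24,
                                  n_iter=150)
        shifted = C.disinhibition_variant(dis, grid=grid, seed=24, n_iter=150)
        # ISI inhibits the FSIN, so at matched drive the pyramidal cell
        # escapes inhibition and fires faster
        assert np.all(shifted.rate_pyr.to_numpy() > base.rate_pyr.to_numpy())

    def test_empty_grid_rejected(self, calibrated_params):
        with pytest.raises(ValueError):
            C.sweep_fsin_drive(calibrated_params, grid=[])

    def test_nonpositive_frequency_rejected(self, calibrated_params):
        with pytest.raises(ValueError):
            C.frequency_sweep(calibrated_params, [0.0, 8.0])

    def test_frequency_sweep_reproducible(self, calibrated_params):
        a = C.frequency_sweep(calibrated_params, [8.0], seed=25, n_iter=30)
        b = C.frequency_sweep(calibrated_params, [8.0], seed=25, n_iter=30)
        assert np.allclose(a.snr, b.snr, equal_nan=True)
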