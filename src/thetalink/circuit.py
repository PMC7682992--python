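"""Feedforward-inhibition circuit model: two leaky integrate-and-fire cells.

A pyramidal output cell and a fast-spiking interneuron (FSIN) receive the
same two Poisson inputs: "hippocampal" spikes whose rate varies sinusoidally
between 0 and 100 Hz at theta frequency (8 Hz), and "noise" spikes at the
constant midpoint rate (50 Hz).  The FSIN inhibits the pyramidal cell.
Excitatory and inhibitory synaptic drives decay with tau_E = 8 ms and
tau_I = 20 ms; both cells share the membrane time constant and threshold.

The questions the model answers: how does the strength of excitatory drive
onto the FSIN shape (i) firing rates, (ii) the correlation of pyramidal
output with each input stream, and (iii) their ratio — the signal-to-noise
of hippocampal transmission?  A disinhibition variant adds an
interneuron-selective interneuron (ISI) that inhibits the FSIN, and a
frequency sweep probes how the SNR depends on the input modulation rate.

All rates are averaged over repeated 1 s iterations with fresh input
realizations (1000 by default).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CircuitParams",
    "InputSpec",
    "OperatingPoint",
    "SimResult",
    "inhomogeneous_poisson",
    "simulate_circuit",
    "simulate_reference",
    "binned_correlation",
    "bin_spikes",
    "calibrate_operating_point",
    "operating_rates",
    "sweep_fsin_drive",
    "disinhibition_variant",
    "frequency_sweep",
]


@dataclass(frozen=True)
class CircuitParams:
    """Integrate-and-fire circuit constants.  Times in ms, potentials in
    threshold units (rest/reset 0, threshold 1); weights are the synaptic
    drive increment per presynaptic spike (inhibitory weights <= 0)."""

    tau_m: float = 20.0
    v_threshold: float = 1.0
    v_reset: float = 0.0
    t_refractory: float = 2.0
    dt: float = 0.1
    tau_e: float = 8.0
    tau_i: float = 20.0
    w_hpc_pyr: float = 0.0
    w_noise_pyr: float = 0.0
    w_hpc_fsin: float = 0.0
    w_noise_fsin: float = 0.0
    w_fsin_pyr: float = 0.0
    # optional disinhibition motif: inputs -> ISI -| FSIN
    w_hpc_isi: float = 0.0
    w_noise_isi: float = 0.0
    w_isi_fsin: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0 or self.tau_m <= 0:
            raise ValueError("time constants must be positive")
        if self.dt >= min(self.tau_e, self.tau_m) / 5:
            raise ValueError("dt too coarse: require dt < min(tau_E, tau_m)/5")
        if self.w_fsin_pyr > 0 or self.w_isi_fsin > 0:
            raise ValueError("inhibitory weights must be <= 0")

    @property
    def has_isi(self) -> bool:
        return self.w_isi_fsin != 0 or self.w_hpc_isi != 0 or self.w_noise_isi != 0


@dataclass(frozen=True)
class InputSpec:
    """Input statistics: hippocampal rate (R/2)(1 - cos 2 pi f t) with
    R = 100 Hz at f = 8 Hz, constant 50 Hz noise, 1 s iterations."""

    rate_max: float = 100.0
    theta_freq: float = 8.0
    noise_rate: float = 50.0
    duration: float = 1.0
    n_iter: int = 1000

    def __post_init__(self) -> None:
        if self.rate_max < 0 or self.noise_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.duration <= 0 or self.n_iter < 1:
            raise ValueError("duration and n_iter must be positive")

    def hpc_rate(self, t_s: np.ndarray) -> np.ndarray:
        return self.rate_max / 2.0 * (1.0 - np.cos(2 * np.pi * self.theta_freq * t_s))


class OperatingPoint(NamedTuple):
    """Calibration targets, Hz."""

    fsin_rate: float = 20.0
    pyr_rate_inhibited: float = 25.0
    pyr_rate_uninhibited: float = 50.0


@dataclass
class SimResult:
    """Spike rasters (n_iter, n_steps) and step size for one simulation."""

    pyr: np.ndarray
    fsin: np.ndarray
    isi: np.ndarray | None
    dt: float
    duration: float

    def rate(self, which: str = "pyr") -> float:
        """Mean firing rate in Hz across iterations."""
        spikes = getattr(self, which)
        return float(spikes.sum(axis=1).mean() / self.duration)


def inhomogeneous_poisson(rate_fn: Callable[[np.ndarray], np.ndarray],
                          duration: float, dt: float,
                          rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Spike times of an inhomogeneous Poisson process by per-bin thinning.

    ``rate_fn`` maps time (s) to rate (Hz); ``dt`` is the bin width in ms.
    Requires rate * dt < 0.2 so the one-spike-per-bin approximation holds.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(duration * 1000.0 / dt))
    t = np.arange(n) * dt / 1000.0
    rate = np.asarray(rate_fn(t), float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0 everywhere")
    p = rate * dt / 1000.0
    if np.any(p >= 0.2):
        raise ValueError("rate * dt >= 0.2: refine dt")
    return t[rng.random(n) < p]


def _input_spike_matrices(spec: InputSpec, dt: float, n_iter: int,
                          rng: np.random.Generator):
    n = int(round(spec.duration * 1000.0 / dt))
    t = np.arange(n) * dt / 1000.0
    p_hpc = spec.hpc_rate(t) * dt / 1000.0
    p_noise = np.full(n, spec.noise_rate * dt / 1000.0)
    if max(p_hpc.max(initial=0), p_noise.max(initial=0)) >= 0.2:
        raise ValueError("rate * dt >= 0.2: refine dt")
    hpc = rng.random((n_iter, n)) < p_hpc
    noise = rng.random((n_iter, n)) < p_noise
    return hpc, noise


def _exc_trace(spikes: np.ndarray, decay: float) -> np.ndarray:
    """Exponentially decaying synaptic trace: s[t] = decay*s[t-1] + spikes[t]."""
    return sps.lfilter([1.0], [1.0, -decay], spikes.astype(float), axis=-1)


def simulate_circuit(params: CircuitParams, spec: InputSpec,
                     seed: int = 0, n_iter: int | None = None,
                     input_spikes: tuple[np.ndarray, np.ndarray] | None = None,
                     return_inputs: bool = False):
    """Simulate the circuit over ``n_iter`` independent 1 s iterations.

    Dynamics per cell: dV/dt = -V/tau_m + I(t), where I is the weighted sum
    of the exponentially decaying input traces; a threshold crossing emits a
    spike, resets V and silences the cell for the refractory period.  Within
    a time step cells update in causal order ISI -> FSIN -> pyramidal, so a
    presynaptic spike inhibits its target from the same step onward.

    ``input_spikes`` overrides the Poisson generation with explicit boolean
    (n_iter, n_steps) rasters (used by the oracle-equivalence tests).
    """
    dt = params.dt
    rng = np.random.default_rng(seed)
    if input_spikes is None:
        m = spec.n_iter if n_iter is None else n_iter
        hpc, noise = _input_spike_matrices(spec, dt, m, rng)
    else:
        hpc, noise = (np.atleast_2d(s) for s in input_spikes)
        m = hpc.shape[0]
    n_steps = hpc.shape[1]
    decay_e = float(np.exp(-dt / params.tau_e))
    decay_i = float(np.exp(-dt / params.tau_i))
    e_hpc = _exc_trace(hpc, decay_e)
    e_noise = _exc_trace(noise, decay_e)

    ref_steps = int(round(params.t_refractory / dt))
    th, reset, tau_m = params.v_threshold, params.v_reset, params.tau_m
    leak = dt / tau_m

    use_isi = params.has_isi
    v_fsin = np.zeros(m)
    v_pyr = np.zeros(m)
    r_fsin = np.zeros(m, dtype=int)
    r_pyr = np.zeros(m, dtype=int)
    fsin_tr = np.zeros(m)
    out_fsin = np.zeros((m, n_steps), dtype=bool)
    out_pyr = np.zeros((m, n_steps), dtype=bool)
    if use_isi:
        v_isi = np.zeros(m)
        r_isi = np.zeros(m, dtype=int)
        isi_tr = np.zeros(m)
        out_isi = np.zeros((m, n_steps), dtype=bool)
    else:
        out_isi = None

    for t in range(n_steps):
        eh, en = e_hpc[:, t], e_noise[:, t]
        fsin_tr *= decay_i
        if use_isi:
            isi_tr *= decay_i
            drive = params.w_hpc_isi * eh + params.w_noise_isi * en
            active = r_isi == 0
            v_isi = np.where(active, v_isi + dt * drive - leak * v_isi, reset)
            r_isi = np.maximum(r_isi - 1, 0)
            sp = active & (v_isi >= th)
            v_isi[sp] = reset
            r_isi[sp] = ref_steps
            out_isi[:, t] = sp
            isi_tr += sp
        drive = (params.w_hpc_fsin * eh + params.w_noise_fsin * en
                 + (params.w_isi_fsin * isi_tr if use_isi else 0.0))
        active = r_fsin == 0
        v_fsin = np.where(active, v_fsin + dt * drive - leak * v_fsin, reset)
        r_fsin = np.maximum(r_fsin - 1, 0)
        sp = active & (v_fsin >= th)
        v_fsin[sp] = reset
        r_fsin[sp] = ref_steps
        out_fsin[:, t] = sp
        fsin_tr += sp

        drive = (params.w_hpc_pyr * eh + params.w_noise_pyr * en
                 + params.w_fsin_pyr * fsin_tr)
        active = r_pyr == 0
        v_pyr = np.where(active, v_pyr + dt * drive - leak * v_pyr, reset)
        r_pyr = np.maximum(r_pyr - 1, 0)
        sp = active & (v_pyr >= th)
        v_pyr[sp] = reset
        r_pyr[sp] = ref_steps
        out_pyr[:, t] = sp

    if not (np.all(np.isfinite(v_pyr)) and np.all(np.isfinite(v_fsin))):
        raise FloatingPointError("non-finite membrane potential: unstable dt/weights")
    duration = n_steps * dt / 1000.0
    result = SimResult(pyr=out_pyr, fsin=out_fsin, isi=out_isi, dt=dt, duration=duration)
    if return_inputs:
        return result, (hpc, noise)
    return result


def simulate_reference(params: CircuitParams, hpc_spikes: np.ndarray,
                       noise_spikes: np.ndarray):
    """Naive per-dt scalar loop with the same update order as the batch
    simulator; used as the independent oracle for spike-for-spike checks."""
    dt = params.dt
    n = len(hpc_spikes)
    decay_e = np.exp(-dt / params.tau_e)
    decay_i = np.exp(-dt / params.tau_i)
    ref_steps = int(round(params.t_refractory / dt))
    leak = dt / params.tau_m
    eh = en = 0.0
    v_f = v_p = 0.0
    r_f = r_p = 0
    fsin_tr = 0.0
    out_f = np.zeros(n, dtype=bool)
    out_p = np.zeros(n, dtype=bool)
    for t in range(n):
        eh = eh * decay_e + (1.0 if hpc_spikes[t] else 0.0)
        en = en * decay_e + (1.0 if noise_spikes[t] else 0.0)
        fsin_tr *= decay_i
        drive = params.w_hpc_fsin * eh + params.w_noise_fsin * en
        if r_f == 0:
            v_f = v_f + dt * drive - leak * v_f
        else:
            v_f = params.v_reset
            r_f -= 1
        if r_f == 0 and v_f >= params.v_threshold:
            v_f = params.v_reset
            r_f = ref_steps
            out_f[t] = True
            fsin_tr += 1.0
        drive = (params.w_hpc_pyr * eh + params.w_noise_pyr * en
                 + params.w_fsin_pyr * fsin_tr)
        if r_p == 0:
            v_p = v_p + dt * drive - leak * v_p
        else:
            v_p = params.v_reset
            r_p -= 1
        if r_p == 0 and v_p >= params.v_threshold:
            v_p = params.v_reset
            r_p = ref_steps
            out_p[t] = True
    return out_p, out_f


def bin_spikes(spikes: np.ndarray, dt: float, bin_width: float = 10.0) -> np.ndarray:
    """Sum a (n_iter, n_steps) raster into bins of ``bin_width`` ms."""
    spikes = np.atleast_2d(spikes)
    per = int(round(bin_width / dt))
    n_bins = spikes.shape[1] // per
    return spikes[:, : n_bins * per].reshape(spikes.shape[0], n_bins, per).sum(axis=2)


def _batch_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation; rows with zero variance give NaN."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=1) / (sa * sb)


def binned_correlation(train_a: np.ndarray, train_b: np.ndarray,
                       dt: float, bin_width: float = 10.0) -> float:
    """Pearson correlation of binned spike counts (mean over iterations).

    Iterations where either binned train has zero variance are excluded;
    if none remain the correlation is reported as 0.
    """
    ca = bin_spikes(train_a, dt, bin_width)
    cb = bin_spikes(train_b, dt, bin_width)
    r = _batch_corr(ca, cb)
    if np.all(np.isnan(r)):
        return 0.0
    return float(np.nanmean(r))


def _rates_for(params: CircuitParams, spec: InputSpec, seed: int, n_iter: int):
    sim = simulate_circuit(params, spec, seed=seed, n_iter=n_iter)
    return sim.rate("pyr"), sim.rate("fsin")


def _bisect_weight(f: Callable[[float], float], target: float,
                   w_max: float = 10.0, iters: int = 30) -> float:
    """Find w with f(w) = target for f monotone increasing, f(0) <= target."""
    lo, hi = 0.0, 1e-3
    while f(hi) < target:
        hi *= 2.0
        if hi > w_max:
            raise ValueError(f"target rate {target} Hz infeasible within weight bounds")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_operating_point(targets: OperatingPoint = OperatingPoint(),
                              spec: InputSpec = InputSpec(),
                              params: CircuitParams = CircuitParams(),
                              seed: int = 0, n_iter_search: int = 200,
                              tolerance: float = 0.10,
                              verify_n_iter: int | None = None) -> CircuitParams:
    """Find weights realizing the target operating point.

    Coordinate bisection exploits rate monotonicity in each weight:
    (1) the shared excitatory weight onto the pyramidal cell is set so the
    uninhibited cell fires at the no-inhibition target; (2) the shared
    excitatory weight onto the FSIN is set to its target rate (the FSIN
    receives no inhibition, so this is independent); (3) the inhibitory
    FSIN -> pyramidal weight is set so the inhibited pyramidal rate matches.
    Search evaluations reuse one seed so each stage bisects a deterministic
    monotone function.  When ``verify_n_iter`` is set, the result is
    re-simulated at that many fresh iterations and a RuntimeError is raised
    if any achieved rate misses its target by more than ``tolerance``
    (relative).
    """
    if targets.pyr_rate_inhibited > targets.pyr_rate_uninhibited:
        raise ValueError("inhibition cannot raise the pyramidal rate: infeasible targets")
    if targets == (0.0, 0.0, 0.0):
        return dataclasses.replace(params, w_hpc_pyr=0.0, w_noise_pyr=0.0,
                                   w_hpc_fsin=0.0, w_noise_fsin=0.0, w_fsin_pyr=0.0)

    def pyr_rate_noinh(w: float) -> float:
        p = dataclasses.replace(params, w_hpc_pyr=w, w_noise_pyr=w,
                                w_hpc_fsin=0.0, w_noise_fsin=0.0, w_fsin_pyr=0.0)
        return _rates_for(p, spec, seed, n_iter_search)[0]

    w_e_pyr = (0.0 if targets.pyr_rate_uninhibited == 0
               else _bisect_weight(pyr_rate_noinh, targets.pyr_rate_uninhibited))

    def fsin_rate(w: float) -> float:
        p = dataclasses.replace(params, w_hpc_fsin=w, w_noise_fsin=w,
                                w_hpc_pyr=0.0, w_noise_pyr=0.0, w_fsin_pyr=0.0)
        return _rates_for(p, spec, seed, n_iter_search)[1]

    w_e_fsin = 0.0 if targets.fsin_rate == 0 else _bisect_weight(fsin_rate, targets.fsin_rate)

    def pyr_rate_inh(w_inh_mag: float) -> float:
        p = dataclasses.replace(params, w_hpc_pyr=w_e_pyr, w_noise_pyr=w_e_pyr,
                                w_hpc_fsin=w_e_fsin, w_noise_fsin=w_e_fsin,
                                w_fsin_pyr=-w_inh_mag)
        return _rates_for(p, spec, seed, n_iter_search)[0]

    if targets.pyr_rate_inhibited == targets.pyr_rate_uninhibited:
        w_inh = 0.0
    else:
        # pyramidal rate decreases in inhibition strength: bisect the negated map
        w_inh = _bisect_weight(lambda w: -pyr_rate_inh(w), -targets.pyr_rate_inhibited)

    calibrated = dataclasses.replace(params, w_hpc_pyr=w_e_pyr, w_noise_pyr=w_e_pyr,
                                     w_hpc_fsin=w_e_fsin, w_noise_fsin=w_e_fsin,
                                     w_fsin_pyr=-w_inh)
    if verify_n_iter:
        achieved = operating_rates(calibrated, spec, seed + 1, verify_n_iter)
        for got, want in zip(achieved, targets):
            ref = abs(want) if want != 0 else 1.0
            if abs(got - want) > tolerance * ref:
                raise RuntimeError(
                    f"calibration verification failed: achieved {achieved}, targets {targets}")
    return calibrated


def operating_rates(params: CircuitParams, spec: InputSpec = InputSpec(),
                    seed: int = 0, n_iter: int | None = None) -> OperatingPoint:
    """Simulated (FSIN, inhibited-pyr, uninhibited-pyr) rates in Hz."""
    n_iter = spec.n_iter if n_iter is None else n_iter
    pyr_inh, fsin = _rates_for(params, spec, seed, n_iter)
    pyr_no, _ = _rates_for(dataclasses.replace(params, w_fsin_pyr=0.0), spec, seed, n_iter)
    return OperatingPoint(fsin, pyr_inh, pyr_no)


def _sweep_point(params, spec, drive, mode, seed, n_iter, bin_width):
    scaled = dataclasses.replace(
        params,
        w_hpc_fsin=params.w_hpc_fsin * drive,
        w_noise_fsin=(params.w_noise_fsin * drive if mode == "parallel"
                      else params.w_noise_fsin),
    )
    sim, (hpc, noise) = simulate_circuit(scaled, spec, seed=seed,
                                         n_iter=n_iter, return_inputs=True)
    r_hpc = _batch_corr(bin_spikes(sim.pyr, sim.dt, bin_width),
                        bin_spikes(hpc, sim.dt, bin_width))
    r_noise = _batch_corr(bin_spikes(sim.pyr, sim.dt, bin_width),
                          bin_spikes(noise, sim.dt, bin_width))
    ch = float(np.nanmean(r_hpc)) if not np.all(np.isnan(r_hpc)) else 0.0
    cn = float(np.nanmean(r_noise)) if not np.all(np.isnan(r_noise)) else 0.0
    row = {
        "drive": drive,
        "rate_pyr": sim.rate("pyr"),
        "rate_fsin": sim.rate("fsin"),
        "corr_hpc": ch,
        "corr_noise": cn,
        "snr": ch / cn if cn != 0 else np.nan,
        "se_corr_hpc": float(np.nanstd(r_hpc) / np.sqrt(np.sum(~np.isnan(r_hpc)) or 1)),
        "se_corr_noise": float(np.nanstd(r_noise) / np.sqrt(np.sum(~np.isnan(r_noise)) or 1)),
        "se_rate_pyr": float(sim.pyr.sum(axis=1).std() / sim.duration / np.sqrt(sim.pyr.shape[0])),
        "se_rate_fsin": float(sim.fsin.sum(axis=1).std() / sim.duration / np.sqrt(sim.fsin.shape[0])),
    }
    if sim.isi is not None:
        row["rate_isi"] = sim.rate("isi")
    return row


def sweep_fsin_drive(params: CircuitParams, spec: InputSpec = InputSpec(),
                     grid: np.ndarray | None = None, mode: str = "parallel",
                     seed: int = 0, n_iter: int | None = None,
                     bin_width: float = 10.0) -> pd.DataFrame:
    """Sweep the FSIN excitatory drive and measure transmission metrics.

    ``grid`` holds multiplicative scale factors applied to the calibrated
    FSIN input weights.  The default spans 0 to 3x the calibrated point:
    past ~3x the pyramidal cell is essentially silenced and the
    input-output correlation ratio is no longer estimable.
    ``mode='parallel'``
    scales hippocampal and noise weights together, ``'hpc_only'`` scales
    only the hippocampal weight.  Per grid point the result row carries the
    mean rates, the binned input-output correlations, their ratio (SNR) and
    Monte-Carlo standard errors.
    """
    if grid is None:
        grid = np.linspace(0.0, 3.0, 13)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty drive grid")
    if mode not in ("parallel", "hpc_only"):
        raise ValueError("mode must be 'parallel' or 'hpc_only'")
    n_iter = spec.n_iter if n_iter is None else n_iter
    rows = [_sweep_point(params, spec, d, mode, seed + i, n_iter, bin_width)
            for i, d in enumerate(grid)]
    return pd.DataFrame(rows)


def disinhibition_variant(params: CircuitParams, spec: InputSpec = InputSpec(),
                          grid: np.ndarray | None = None, seed: int = 0,
                          n_iter: int | None = None,
                          bin_width: float = 10.0) -> pd.DataFrame:
    """FSIN-drive sweep with the ISI disinhibition motif active.

    ``params`` must carry the ISI weights (inputs -> ISI excitatory,
    ISI -> FSIN inhibitory); with all three at zero this reduces exactly to
    :func:`sweep_fsin_drive`.
    """
    return sweep_fsin_drive(params, spec, grid=grid, mode="parallel",
                            seed=seed, n_iter=n_iter, bin_width=bin_width)


def frequency_sweep(params: CircuitParams, f_values,
                    spec: InputSpec = InputSpec(), seed: int = 0,
                    n_iter: int | None = None, bin_width: float = 10.0) -> pd.DataFrame:
    """SNR at the calibrated drive as a function of input modulation frequency."""
    f_values = np.asarray(f_values, float)
    if np.any(f_values <= 0):
        raise ValueError("modulation frequencies must be positive")
    n_iter = spec.n_iter if n_iter is None else n_iter
    rows = []
    for i, f in enumerate(f_values):
        sp = dataclasses.replace(spec, theta_freq=float(f))
        row = _sweep_point(params, sp, 1.0, "parallel", seed + i, n_iter, bin_width)
        row["freq"] = float(f)
        rows.append(row)
    return pd.DataFrame(rows)
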