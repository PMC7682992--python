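"""Quantification of optically evoked intracellular responses.

Works on single traces from voltage-clamp (currents, pA) or current-clamp
(potentials, mV) recordings during an 8 Hz light-flash train: total charge
of the evoked current, paired-pulse ratio, first-spike latency and evoked
spike counts.  The 8 Hz train gives a 125 ms inter-stimulus interval, which
is the default per-pulse response window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EvokedTrace",
    "total_charge",
    "paired_pulse_ratio",
    "first_spike_latency",
    "count_evoked_spikes",
    "resting_potential",
    "input_resistance",
]

#: inter-stimulus interval of the 8 Hz flash train, seconds
DEFAULT_ISI = 0.125


@dataclass
class EvokedTrace:
    """A sampled trace with its stimulus times and baseline window.

    ``values`` are pA (voltage clamp) or mV (current clamp); ``stim_times``
    are flash onsets (s); ``baseline`` is a (start, stop) window in s that
    precedes the first stimulus.
    """

    time: np.ndarray
    values: np.ndarray
    stim_times: np.ndarray
    baseline: tuple[float, float] = (0.0, 0.0)
    current_clamp: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.values = np.asarray(self.values, float)
        self.stim_times = np.atleast_1d(np.asarray(self.stim_times, float))
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must match")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling interval must be constant")
        if self.stim_times.size and (
            self.stim_times.min() < self.time[0] or self.stim_times.max() > self.time[-1]
        ):
            raise ValueError("stimulus times outside trace")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def _baseline_value(self) -> float:
        a, b = self.baseline
        if b <= a:
            return 0.0
        m = (self.time >= a) & (self.time < b)
        return float(self.values[m].mean()) if m.any() else 0.0

    def window(self, start: float, stop: float) -> np.ndarray:
        m = (self.time >= start) & (self.time < stop)
        return self.values[m]


def total_charge(trace: EvokedTrace, window: tuple[float, float]) -> float:
    """Charge of the baseline-subtracted current over ``window``, in pC.

    The integral of pA over s is pC; the magnitude is reported, so inward
    (negative) currents give positive charge.
    """
    if trace.current_clamp:
        raise ValueError("charge is defined for voltage-clamp (current) traces")
    a, b = window
    if a < trace.time[0] or b > trace.time[-1] + 1.0 / trace.fs:
        raise ValueError("response window outside trace")
    m = (trace.time >= a) & (trace.time < b)
    seg = trace.values[m] - trace._baseline_value()
    return float(abs(np.trapezoid(seg, dx=1.0 / trace.fs)))


def _peak_amplitude(trace: EvokedTrace, start: float, stop: float) -> float:
    """Extremum (|max deflection|) of the low-passed, baseline-subtracted segment."""
    seg = trace.window(start, stop) - trace._baseline_value()
    if seg.size == 0:
        return 0.0
    if trace.fs > 2000.0:  # 1 kHz low-pass for noise-robust peaks
        sos = sps.butter(4, 1000.0, fs=trace.fs, output="sos")
        seg = sps.sosfiltfilt(sos, seg)
    return float(seg[np.argmax(np.abs(seg))])


def paired_pulse_ratio(trace: EvokedTrace, stim1: float | None = None,
                       stim2: float | None = None, isi: float | None = None) -> float:
    """Second/first peak amplitude ratio of successive evoked responses.

    Measurement windows equal the inter-stimulus interval, so the two
    responses cannot overlap.  Ratio > 1 is facilitation, < 1 depression.
    """
    if stim1 is None or stim2 is None:
        if trace.stim_times.size < 2:
            raise ValueError("need two stimulus times")
        stim1, stim2 = float(trace.stim_times[0]), float(trace.stim_times[1])
    if isi is None:
        isi = stim2 - stim1
    if stim2 - stim1 < isi - 1e-12:
        raise ValueError("measurement windows overlap")
    p1 = _peak_amplitude(trace, stim1, stim1 + isi)
    p2 = _peak_amplitude(trace, stim2, stim2 + isi)
    if p1 == 0:
        warnings.warn("zero first-pulse amplitude: PPR undefined, returning nan")
        return float("nan")
    return p2 / p1


def _upward_crossings(v: np.ndarray, threshold: float) -> np.ndarray:
    return np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1


def first_spike_latency(trace: EvokedTrace, stim_time: float,
                        threshold: float = 0.0, isi: float = DEFAULT_ISI) -> float | None:
    """Latency (ms) from a flash to the first upward threshold crossing.

    Searches one inter-stimulus interval; returns None when the cell does
    not spike.
    """
    if not trace.current_clamp:
        raise ValueError("spike latency is defined for current-clamp traces")
    m = (trace.time >= stim_time) & (trace.time < stim_time + isi)
    idx = _upward_crossings(trace.values[m], threshold)
    if idx.size == 0:
        return None
    return float(idx[0] / trace.fs * 1000.0)


def count_evoked_spikes(trace: EvokedTrace, threshold: float = 0.0,
                        isi: float = DEFAULT_ISI, refractory: float = 1e-3) -> int:
    """Total threshold crossings across all inter-stimulus intervals.

    Crossings closer than ``refractory`` (1 ms deadtime) count once.
    """
    if not trace.current_clamp:
        raise ValueError("spike counting is defined for current-clamp traces")
    total = 0
    for t0 in trace.stim_times:
        m = (trace.time >= t0) & (trace.time < t0 + isi)
        idx = _upward_crossings(trace.values[m], threshold)
        if idx.size == 0:
            continue
        kept = [idx[0]]
        dead = refractory * trace.fs
        for i in idx[1:]:
            if i - kept[-1] >= dead:
                kept.append(i)
        total += len(kept)
    return total


def resting_potential(time: np.ndarray, voltage: np.ndarray,
                      window: tuple[float, float]) -> float:
    """Mean membrane potential over a stimulus-free window (mV)."""
    time = np.asarray(time, float)
    m = (time >= window[0]) & (time < window[1])
    return float(np.asarray(voltage, float)[m].mean())


def input_resistance(step_current_pA: float, v_baseline_mV: float,
                     v_steady_mV: float) -> float:
    """Input resistance (MOhm) from a current step: dV / I."""
    if step_current_pA == 0:
        raise ValueError("step current must be nonzero")
    return (v_steady_mV - v_baseline_mV) / step_current_pA * 1000.0
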