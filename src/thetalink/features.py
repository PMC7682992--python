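"""Band-limited LFP features: power, synchrony, and cross-frequency coupling.

The feature set mirrors the standard two-region catalogue used for
hippocampal-prefrontal LFP analysis:

* 16 single-frequency measures — band power per region, amplitude covariation
  and weighted phase-lag index (WPLI) between regions, over theta (4-12 Hz),
  beta (13-30 Hz), low gamma (30-55 Hz) and high gamma (65-100 Hz);
* 24 cross-frequency (phase-amplitude) measures — modulation of beta / low
  gamma / high gamma amplitude by low-band phase (theta 2-6 Hz, alpha
  6-10 Hz), over all four ordered region pairs.

Filtering is zero-phase FIR (Hamming window, length 3x the period of the
band's low edge); instantaneous amplitude and phase come from the Hilbert
transform with half a filter length trimmed from each end, where the
transient of the FIR kernel corrupts the analytic signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session import PairedRecording

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "AnalyticSignal",
    "DynamicWindowSpec",
    "SINGLE_BANDS",
    "LOW_BANDS",
    "HIGH_BANDS",
    "FEATURE_NAMES",
    "bandpass",
    "fir_length",
    "analytic",
    "band_analytic",
    "band_power",
    "wpli",
    "lead_lag_sign",
    "amplitude_covariation",
    "cfc",
    "session_analytics",
    "compute_feature_table",
    "windowed_features",
    "zscore_event_dynamics",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [lo, hi] in Hz with a display name."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"require 0 < lo < hi, got [{self.lo}, {self.hi}]")

    def validate_fs(self, fs: float) -> None:
        if self.hi > fs / 2:
            raise ValueError(f"band {self.name} exceeds Nyquist ({fs / 2} Hz)")


#: Single-frequency bands (power / WPLI / amplitude covariation).
SINGLE_BANDS = (
    BandSpec("Theta", 4.0, 12.0),
    BandSpec("Beta", 13.0, 30.0),
    BandSpec("LowGamma", 30.0, 55.0),
    BandSpec("HighGamma", 65.0, 100.0),
)

#: Low (phase-providing) bands for cross-frequency coupling.  Note "Theta"
#: here is the 2-6 Hz phase band, distinct from the 4-12 Hz power band.
LOW_BANDS = (BandSpec("Theta", 2.0, 6.0), BandSpec("Alpha", 6.0, 10.0))

#: High (amplitude-providing) bands for cross-frequency coupling.
HIGH_BANDS = (BandSpec("Beta", 13.0, 30.0), BandSpec("LowGamma", 30.0, 55.0),
              BandSpec("HighGamma", 65.0, 100.0))

_REGIONS = ("hpc", "pfc")


def _build_feature_names() -> list[str]:
    names = [f"pow_{r}{b.name}" for r in _REGIONS for b in SINGLE_BANDS]
    names += [f"ampcov_hpcPfc{b.name}" for b in SINGLE_BANDS]
    names += [f"wpli_hpcPfc{b.name}" for b in SINGLE_BANDS]
    for phase_region in _REGIONS:
        for amp_region in _REGIONS:
            for lo in LOW_BANDS:
                for hi in HIGH_BANDS:
                    names.append(
                        f"cfc_{phase_region}{lo.name}_{amp_region}{hi.name}"
                    )
    return names


#: The 40 feature names, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = tuple(_build_feature_names())
assert len(FEATURE_NAMES) == 40


@dataclass
class AnalyticSignal:
    """Instantaneous amplitude/phase of a band-limited signal.

    ``offset`` counts samples trimmed from the start of the parent signal
    (the same number is trimmed from the end); index ``i`` of ``amplitude``
    corresponds to absolute sample ``i + offset``.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    fs: float
    offset: int = 0

    @property
    def n(self) -> int:
        return self.amplitude.size


@dataclass(frozen=True)
class DynamicWindowSpec:
    """Sliding-window grid for event-locked dynamics.

    2.5 s windows advanced at 1.5 s steps from 7.5 s before to 7.5 s after
    the event give an 11-point grid.
    """

    window: float = 2.5
    step: float = 1.5
    span: float = 7.5

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.span <= 0:
            raise ValueError("window, step and span must be positive")
        k = self.span / self.step
        if abs(k - round(k)) > 1e-9:
            raise ValueError("span must be an integer multiple of step")

    @property
    def offsets(self) -> np.ndarray:
        """Grid-point times relative to the event (t=0 at the event)."""
        return np.arange(-round(self.span / self.step), round(self.span / self.step) + 1) * self.step


def fir_length(band: BandSpec, fs: float) -> int:
    """Filter length: 3x the period of the band's low edge, forced odd."""
    n = int(round(3 * fs / band.lo))
    return n + 1 if n % 2 == 0 else n


def _fir_kernel(band: BandSpec, fs: float) -> np.ndarray:
    band.validate_fs(fs)
    return sps.firwin(fir_length(band, fs), [band.lo, band.hi], pass_zero=False,
                      window="hamming", fs=fs)


def bandpass(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase band-limited copy of ``x`` (same length).

    The FIR kernel is applied forward and backward (via one convolution with
    its autocorrelation), so the passband response is |H|^2 and the phase
    response is identically zero.
    """
    x = np.asarray(x, dtype=float)
    h = _fir_kernel(band, fs)
    if x.size <= h.size:
        raise ValueError(f"signal length {x.size} <= filter length {h.size}")
    h2 = np.convolve(h, h[::-1])
    return sps.fftconvolve(x, h2, mode="same")


def analytic(filtered: np.ndarray, fs: float, offset: int = 0) -> AnalyticSignal:
    """Hilbert amplitude and phase of a band-limited signal."""
    z = sps.hilbert(np.asarray(filtered, dtype=float))
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z), fs=fs, offset=offset)


def band_analytic(x: np.ndarray, band: BandSpec, fs: float, trim: bool = True) -> AnalyticSignal:
    """Filter ``x`` into ``band`` and return its analytic decomposition.

    With ``trim=True`` (default) half a filter length is dropped from each
    end before the Hilbert transform; the result records the dropped count
    in ``offset`` so windows can still be indexed in absolute samples.
    """
    xf = bandpass(x, band, fs)
    edge = fir_length(band, fs) // 2 if trim else 0
    if trim and xf.size <= 2 * edge:
        raise ValueError("signal too short to trim filter edges")
    return analytic(xf[edge: xf.size - edge] if trim else xf, fs, offset=edge)


def band_power(x: np.ndarray, band: BandSpec, fs: float, segment_length: float = 2.0) -> float:
    """Band power from Welch's PSD with nonoverlapping segments.

    Integrates the density over the closed interval [lo, hi]; for a unit
    sinusoid inside the band this recovers the tone variance (0.5).
    """
    x = np.asarray(x, dtype=float)
    band.validate_fs(fs)
    nperseg = int(round(segment_length * fs))
    if nperseg > x.size:
        raise ValueError("segment longer than signal")
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=0)
    mask = (f >= band.lo) & (f <= band.hi)
    return float(np.sum(pxx[mask]) * (f[1] - f[0]))


def _cross_term_parts(x, y, band, fs):
    """(|S|, Im S) of the per-sample cross-term S = z_x conj(z_y).

    Im S is computed as A_x A_y sin(phi_x - phi_y) so bit-identical phases
    give exactly zero (the stated zero-lag convention), not rounding noise.
    """
    za = band_analytic(x, band, fs)
    zb = band_analytic(y, band, fs)
    mag = za.amplitude * zb.amplitude
    return mag, mag * np.sin(za.phase - zb.phase)


def _wpli_from_imag(im: np.ndarray, debias: bool = False) -> float:
    denom = np.mean(np.abs(im))
    if denom == 0:
        return 0.0
    if debias:
        num = np.mean(im) ** 2 - np.mean(im**2) / im.size
        den2 = np.mean(np.abs(im)) ** 2 - np.mean(im**2) / im.size
        return float(num / den2) if den2 > 0 else 0.0
    return float(np.abs(np.mean(im)) / denom)


def wpli(x: np.ndarray, y: np.ndarray, band: BandSpec, fs: float, debias: bool = False) -> float:
    """Weighted phase-lag index between two channels in a band, in [0, 1].

    WPLI = |mean(Im S)| / mean(|Im S|) with per-sample cross-term
    S = z_x conj(z_y) from the band-limited analytic signals.  Zero-lag
    (purely real) coupling gives Im S = 0 everywhere and returns 0 by
    convention.  ``debias=True`` switches to the debiased squared estimator.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    _, im = _cross_term_parts(x, y, band, fs)
    return _wpli_from_imag(im, debias=debias)


def lead_lag_sign(x: np.ndarray, y: np.ndarray, band: BandSpec, fs: float,
                  atol: float = 1e-12) -> str:
    """Which channel leads, from the sign of mean(Im S), S = z_x conj(z_y).

    Positive mean imaginary part means ``x`` leads (convention: x = vHPC).
    Returns one of ``"x_leads"``, ``"y_leads"``, ``"indeterminate"``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    mag, im = _cross_term_parts(x, y, band, fs)
    m = float(np.mean(im))
    scale = float(np.mean(mag)) or 1.0
    if abs(m) <= atol * scale:
        return "indeterminate"
    return "x_leads" if m > 0 else "y_leads"


def amplitude_covariation(x: np.ndarray, y: np.ndarray, band: BandSpec, fs: float) -> float:
    """Pearson correlation of the two instantaneous band amplitudes."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    a = band_analytic(x, band, fs).amplitude
    b = band_analytic(y, band, fs).amplitude
    return _safe_corr(a, b)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant amplitude: correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _mi_from_phase_amp(phase: np.ndarray, amp: np.ndarray) -> float:
    total = np.sum(amp)
    if total == 0:
        warnings.warn("all-zero high-band amplitude: MI undefined, returning 0")
        return 0.0
    return float(np.abs(np.sum(amp * np.exp(1j * phase))) / total)


def cfc(phase_sig: np.ndarray, low_band: BandSpec, amp_sig: np.ndarray,
        high_band: BandSpec, fs: float) -> float:
    """Phase-amplitude modulation index in [0, 1].

    The high-band amplitude at each sample weights a unit vector at the
    low-band phase; MI is the length of the mean resultant, normalized by
    the summed amplitudes:  MI = |sum A e^{i phi}| / sum A.  For amplitude
    A = 1 + m cos(phi) with uniform phase coverage the limit is m/2.
    """
    phase_sig, amp_sig = np.asarray(phase_sig, float), np.asarray(amp_sig, float)
    if phase_sig.shape != amp_sig.shape:
        raise ValueError("signals must have equal length")
    lo = band_analytic(phase_sig, low_band, fs)
    hi = band_analytic(amp_sig, high_band, fs)
    start = max(lo.offset, hi.offset)
    stop = phase_sig.size - start
    phase = lo.phase[start - lo.offset: stop - lo.offset]
    amp = hi.amplitude[start - hi.offset: stop - hi.offset]
    return _mi_from_phase_amp(phase, amp)


# ---------------------------------------------------------------------------
# Session-level bulk computation
# ---------------------------------------------------------------------------

def session_analytics(rec: PairedRecording) -> dict[tuple[str, str], AnalyticSignal]:
    """All band-limited analytic signals a session's feature set needs.

    Returns a dict keyed by (region, band_key) where band_key is the band
    name for the single-frequency set and ``"low"+name`` for the 2-6 /
    6-10 Hz phase bands.
    """
    out: dict[tuple[str, str], AnalyticSignal] = {}
    for region, x in (("hpc", rec.hpc), ("pfc", rec.pfc)):
        for band in SINGLE_BANDS:
            out[(region, band.name)] = band_analytic(x, band, rec.fs)
        for band in LOW_BANDS:
            out[(region, "low" + band.name)] = band_analytic(x, band, rec.fs)
    return out


def _window_slices(an: AnalyticSignal, i0: int, i1: int) -> np.ndarray:
    return slice(i0 - an.offset, i1 - an.offset)


def _features_for_window(analytics, i0: int, i1: int) -> np.ndarray:
    """All 40 features on absolute-sample window [i0, i1)."""
    vals = np.empty(len(FEATURE_NAMES))
    j = 0
    # power: mean squared Hilbert envelope (proportional to band variance)
    for region in _REGIONS:
        for band in SINGLE_BANDS:
            a = analytics[(region, band.name)]
            vals[j] = np.mean(a.amplitude[_window_slices(a, i0, i1)] ** 2)
            j += 1
    for band in SINGLE_BANDS:  # amplitude covariation
        a = analytics[("hpc", band.name)]
        b = analytics[("pfc", band.name)]
        aw = a.amplitude[_window_slices(a, i0, i1)]
        bw = b.amplitude[_window_slices(b, i0, i1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals[j] = _safe_corr(aw, bw)
        j += 1
    for band in SINGLE_BANDS:  # WPLI
        a = analytics[("hpc", band.name)]
        b = analytics[("pfc", band.name)]
        sl_a, sl_b = _window_slices(a, i0, i1), _window_slices(b, i0, i1)
        im = (a.amplitude[sl_a] * b.amplitude[sl_b]
              * np.sin(a.phase[sl_a] - b.phase[sl_b]))
        vals[j] = _wpli_from_imag(im)
        j += 1
    for phase_region in _REGIONS:  # cross-frequency coupling
        for amp_region in _REGIONS:
            for lo in LOW_BANDS:
                p = analytics[(phase_region, "low" + lo.name)]
                pw = p.phase[_window_slices(p, i0, i1)]
                for hi in HIGH_BANDS:
                    a = analytics[(amp_region, hi.name)]
                    aw = a.amplitude[_window_slices(a, i0, i1)]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        vals[j] = _mi_from_phase_amp(pw, aw)
                    j += 1
    return vals


def _max_offset(analytics) -> int:
    return max(a.offset for a in analytics.values())


def compute_feature_table(rec: PairedRecording,
                          window: float = 2.5,
                          step: float = 1.5,
                          analytics=None):
    """Continuous windowed feature time series across a whole session.

    Windows of ``window`` s advanced by ``step`` s, restricted to the region
    where every band's filter transient has been trimmed.  Returns
    ``(times, values)`` where ``times`` are window centers (s) and ``values``
    is (n_windows, 40) in :data:`FEATURE_NAMES` order.
    """
    if analytics is None:
        analytics = session_analytics(rec)
    off = _max_offset(analytics)
    w = int(round(window * rec.fs))
    s = int(round(step * rec.fs))
    starts = np.arange(off, rec.n_samples - off - w + 1, s)
    if starts.size == 0:
        raise ValueError("session too short for a single window")
    values = np.stack([_features_for_window(analytics, i, i + w) for i in starts])
    times = (starts + w / 2) / rec.fs
    return times, values


def windowed_features(rec: PairedRecording, events: np.ndarray,
                      spec: DynamicWindowSpec = DynamicWindowSpec(),
                      analytics=None):
    """Event-locked feature grids: 11 window centers from -7.5 to +7.5 s.

    Each of the 40 features is evaluated in a ``spec.window``-long window
    centered on each grid point around each event.  Events whose full grid
    (plus filter edges) does not fit inside the session are dropped and
    logged.  Returns ``(kept_event_times, grids)`` with ``grids`` of shape
    (n_events, 11, 40).
    """
    if analytics is None:
        analytics = session_analytics(rec)
    off = _max_offset(analytics)
    half_w = spec.window / 2
    offsets = spec.offsets
    grids, kept = [], []
    for t0 in np.atleast_1d(np.asarray(events, float)):
        lo_t = t0 + offsets[0] - half_w
        hi_t = t0 + offsets[-1] + half_w
        if lo_t * rec.fs < off or hi_t * rec.fs > rec.n_samples - off:
            logger.warning("event at %.2f s too close to session edge; dropped", t0)
            continue
        grid = np.empty((offsets.size, len(FEATURE_NAMES)))
        for gi, dt in enumerate(offsets):
            i0 = int(round((t0 + dt - half_w) * rec.fs))
            grid[gi] = _features_for_window(analytics, i0, i0 + int(round(spec.window * rec.fs)))
        grids.append(grid)
        kept.append(t0)
    if not grids:
        raise ValueError("no events far enough from session edges")
    return np.asarray(kept), np.stack(grids)


def zscore_event_dynamics(grid: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Z-score each run's grid relative to the rest of that run.

    ``grid`` is a single 11-point vector, a stack of runs (n_runs, 11), or
    stacked feature grids (n_runs, 11, n_features); pass ``axis`` to
    override which axis holds the grid points.  A zero-variance run returns
    all zeros with a warning.
    """
    g = np.asarray(grid, float)
    if axis is None:
        axis = 0 if g.ndim == 1 else 1
    mu = g.mean(axis=axis, keepdims=True)
    sd = g.std(axis=axis, keepdims=True)
    bad = sd == 0
    if np.any(bad):
        warnings.warn("zero-variance run(s): z-scores set to 0")
    sd = np.where(bad, 1.0, sd)
    out = (g - mu) / sd
    return np.where(np.broadcast_to(bad, out.shape), 0.0, out)
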