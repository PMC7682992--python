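"""Synthetic two-channel LFP + elevated-plus-maze sessions with known truth.

The generator emulates the study conditions of a 15-min EPM trial recorded
at 2000 Hz from ventral hippocampus (vHPC) and medial prefrontal cortex
(mPFC): a 1/f background, a narrowband ~8 Hz theta rhythm with a visible
vHPC spectral peak, controllable theta phase coupling between the channels
(with vHPC leading), controllable theta-phase -> beta/gamma-amplitude
coupling, and a genotype-dependent boost of both couplings as the animal
approaches the maze center.  Wild-type sessions ramp coupling around
closed-arm -> center entries; heterozygous sessions are flat and carry a
global coupling reduction, mimicking the baseline deficit.

Every stochastic ingredient is driven by one seed, so identical configs
give bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import behavior as beh
from .features import BandSpec, HIGH_BANDS, bandpass
from .session import BehaviorTrack, GroundTruth, PairedRecording, Session

__all__ = [
    "SynthConfig",
    "generate_lfp_pair",
    "generate_epm_session",
    "generate_session",
    "generate_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the emulated study conditions.

    Parameters
    ----------
    fs : samples/s of the LFP pair.
    duration : session length in s (a single 15-min trial by default).
    theta_freq : center of the narrowband theta rhythm, Hz.
    theta_snr : vHPC theta amplitude as a multiple of the 4-12 Hz
        background RMS; controls how far the theta peak stands above the
        1/f floor.
    coupling_strength : fraction of the shared theta process driving the
        mPFC channel, in [0, 1].
    phase_lag : theta phase lead of vHPC over mPFC, radians (positive =
        vHPC leads).
    cfc_depth : modulation depth m in [0, 1] of high-band amplitude by
        theta phase: A(t) = 1 + m cos(phase).
    approach_gain : multiplicative boost of coupling_strength and cfc_depth
        at the peak of the center-approach ramp (WT > 1; Het = 1).
    coupling_scale : global multiplier on both couplings (Het sessions use
        a reduced value to carry the baseline deficit).
    noise_exponent : spectral exponent of the 1/f^a background.
    open_frac : target open-arm occupancy fraction of the trajectory.
    track_fs : position-tracking rate, samples/s.
    seed : master seed for all randomness.
    """

    fs: float = 2000.0
    duration: float = 900.0
    theta_freq: float = 8.0
    theta_snr: float = 4.0
    coupling_strength: float = 0.35
    phase_lag: float = 0.5
    cfc_depth: float = 0.4
    approach_gain: float = 2.5
    coupling_scale: float = 1.0
    noise_exponent: float = 1.0
    open_frac: float = 0.15
    track_fs: float = 25.0
    seed: int = 0
    # slow multiplicative drift of both couplings (gives the network stage
    # time-varying, heavy-tailed sources to separate)
    slow_mod_sd: float = 0.45
    slow_mod_tau: float = 10.0

    def __post_init__(self) -> None:
        vals = [self.fs, self.duration, self.theta_freq, self.theta_snr,
                self.coupling_strength, self.phase_lag, self.cfc_depth,
                self.approach_gain, self.coupling_scale, self.noise_exponent,
                self.open_frac, self.track_fs]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite config value")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must be in [0, 1]")
        if not 0 <= self.cfc_depth <= 1:
            raise ValueError("cfc_depth must be in [0, 1]")
        if not 0 <= self.open_frac <= 1:
            raise ValueError("open_frac must be in [0, 1]")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration x fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        import yaml

        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f)


def _pink_noise(n: int, exponent: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^a noise by spectral shaping of white noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    shape = np.ones_like(freqs)
    nz = freqs > 0
    # flatten below 0.5 Hz so the DC region does not dominate the variance
    shape[nz] = np.maximum(freqs[nz], 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _drifting_phase(n: int, f0: float, fs: float, rng: np.random.Generator,
                    drift_sd: float = 1.2) -> np.ndarray:
    """Phase of a narrowband process: linear ramp at f0 + slow random walk.

    The Wiener phase drift (``drift_sd`` rad/sqrt(s)) broadens the line so
    instantaneous-phase statistics are nondegenerate.
    """
    dt = 1.0 / fs
    walk = np.cumsum(rng.standard_normal(n)) * (drift_sd * np.sqrt(dt))
    return 2 * np.pi * f0 * np.arange(n) * dt + walk


def _slow_modulation(n: int, fs: float, sd: float, tau: float,
                     rng: np.random.Generator,
                     burst_rate: float = 1.0 / 25.0) -> np.ndarray:
    """Zero-mean bursty drift: sparse exponential-amplitude shot noise
    smoothed by a ``tau``-s decay, standardized to the requested SD.

    Burstiness matters: the coupling and phase-amplitude modulation traces
    act as the latent sources the ICA stage must separate, and a Gaussian
    (e.g. Ornstein-Uhlenbeck) drift would make them unidentifiable.
    """
    if sd == 0:
        return np.zeros(n)
    n_events = rng.poisson(burst_rate * n / fs)
    if n_events == 0:
        return np.zeros(n)
    train = np.zeros(n)
    idx = rng.integers(0, n, n_events)
    np.add.at(train, idx, rng.exponential(1.0, n_events))
    a = np.exp(-1.0 / (fs * tau))
    x = sps.lfilter([1.0], [1.0, -a], train)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _approach_ramp(n: int, fs: float, event_times: np.ndarray,
                   rise: float = 3.0, decay: float = 1.5,
                   amplitudes: np.ndarray | None = None) -> np.ndarray:
    """Per-sample ramp: linear rise over ``rise`` s before each event, peak
    at the event, linear decay over ``decay`` s after.

    ``amplitudes`` scales each event's peak individually (default 1);
    event-to-event variability keeps the coupling and phase-amplitude ramps
    from being copies of one another.
    """
    ramp = np.zeros(n)
    events = np.atleast_1d(event_times)
    if amplitudes is None:
        amplitudes = np.ones(events.size)
    for t0, amp in zip(events, amplitudes):
        i0 = int(round((t0 - rise) * fs))
        ip = int(round(t0 * fs))
        i1 = int(round((t0 + decay) * fs))
        up = np.linspace(0, 1, max(ip - i0, 1), endpoint=False)
        down = np.linspace(1, 0, max(i1 - ip, 1), endpoint=False)
        seg = np.concatenate([up, down])
        a = max(i0, 0)
        b = min(i1, n)
        if a >= b:
            continue
        ramp[a:b] = np.maximum(ramp[a:b], amp * seg[a - i0: b - i0])
    return ramp


_CARRIER_FREQS = {"Beta": 20.0, "LowGamma": 42.0, "HighGamma": 80.0}


def generate_lfp_pair(config: SynthConfig,
                      event_times: np.ndarray | None = None,
                      genotype: str = "wt",
                      rng: np.random.Generator | None = None
                      ) -> tuple[PairedRecording, GroundTruth]:
    """Synthesize a paired vHPC/mPFC recording with known coupling traces.

    Each channel is 1/f background + narrowband theta + three
    amplitude-modulated high-band carriers (beta / low gamma / high gamma).
    The mPFC theta is a ``coupling``-weighted mix of the shared (vHPC)
    theta, delayed by ``phase_lag``, and an independent theta process; the
    carrier envelopes are ``1 + m(t) cos(theta phase)`` with the vHPC theta
    phase on both channels.  ``coupling`` and ``m`` ramp around
    ``event_times`` by ``approach_gain`` and drift slowly, and both traces
    are returned as ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, fs = config.n_samples, config.fs
    events = np.asarray(event_times, float) if event_times is not None else np.empty(0)

    bg_hpc = _pink_noise(n, config.noise_exponent, fs, rng)
    bg_pfc = _pink_noise(n, config.noise_exponent, fs, rng)

    # independent per-event boost amplitudes and independent slow drifts:
    # the two coupling traces ramp at the same approaches on average but
    # are not copies, so the ICA stage faces two distinct latent sources
    boost = config.approach_gain - 1.0
    amp_c = 0.4 + rng.exponential(0.6, events.size)
    amp_m = 0.4 + rng.exponential(0.6, events.size)
    gain_c = 1.0 + boost * _approach_ramp(n, fs, events, amplitudes=amp_c)
    gain_m = 1.0 + boost * _approach_ramp(n, fs, events, amplitudes=amp_m)
    slow_c = _slow_modulation(n, fs, config.slow_mod_sd, config.slow_mod_tau, rng)
    slow_m = _slow_modulation(n, fs, config.slow_mod_sd, config.slow_mod_tau, rng)
    coupling = np.clip(
        config.coupling_strength * config.coupling_scale * gain_c * (1 + slow_c), 0, 1)
    cfc_depth = np.clip(
        config.cfc_depth * config.coupling_scale * gain_m * (1 + slow_m), 0, 1)

    theta_band = BandSpec("Theta", 4.0, 12.0)
    a_theta = config.theta_snr * bandpass(bg_hpc, theta_band, fs).std()
    # ~2 Hz theta linewidth: wide enough that independent channels'
    # phase difference decorrelates within seconds (nondegenerate WPLI
    # null), narrow enough for a distinct spectral peak
    phi_shared = _drifting_phase(n, config.theta_freq, fs, rng, drift_sd=3.5)
    phi_indep = _drifting_phase(n, config.theta_freq, fs, rng, drift_sd=3.5)
    hpc = bg_hpc + a_theta * np.cos(phi_shared)
    pfc_theta = (coupling * np.cos(phi_shared - config.phase_lag)
                 + np.sqrt(1 - coupling**2) * np.cos(phi_indep))
    pfc = bg_pfc + a_theta * pfc_theta

    envelope = 1.0 + cfc_depth * np.cos(phi_shared)
    for band in HIGH_BANDS:
        f_c = _CARRIER_FREQS[band.name]
        # carriers well above the background in-band RMS so the measured
        # envelope modulation is not swamped by the 1/f floor
        a_hpc = 3.5 * bandpass(bg_hpc, band, fs).std()
        a_pfc = 3.5 * bandpass(bg_pfc, band, fs).std()
        hpc = hpc + a_hpc * envelope * np.cos(_drifting_phase(n, f_c, fs, rng, 4.0))
        pfc = pfc + a_pfc * envelope * np.cos(_drifting_phase(n, f_c, fs, rng, 4.0))

    rec = PairedRecording(hpc=hpc, pfc=pfc, fs=fs, meta={"genotype": genotype})
    truth = GroundTruth(coupling=coupling, cfc_depth=cfc_depth,
                        event_times=events, genotype=genotype)
    return rec, truth


def generate_epm_session(config: SynthConfig,
                         geometry: beh.EPMGeometry = beh.EPMGeometry(),
                         rng: np.random.Generator | None = None) -> BehaviorTrack:
    """Random-walk EPM trajectory with controlled open-arm occupancy.

    The animal starts in the center, alternates arm visits with brief
    center dwells, and chooses the next arm class by bang-bang feedback on
    the running open-time fraction, so the measured fraction converges to
    ``config.open_frac``.  Closed-arm dwells are floored at 2 s, so a
    15-min session yields dozens of closed-arm -> center approaches.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.track_fs
    n_total = int(round(config.duration * fs))
    speed = 10.0  # cm/s along the arm centerline
    xs, ys = [], []
    open_samples = 0

    def axis_xy(arm_axis: str, sign: int, along: np.ndarray, across: np.ndarray):
        if arm_axis == geometry.open_axis:
            return sign * along, across
        return across, sign * along

    def emit(x_arr, y_arr):
        nonlocal open_samples
        xs.append(x_arr)
        ys.append(y_arr)
        zones, _ = geometry.zone_and_arm(x_arr, y_arr)
        open_samples += int(np.sum(zones == beh.OPEN))

    def dwell(x0, y0, dur):
        m = max(int(round(dur * fs)), 1)
        jit = 0.4
        emit(x0 + jit * rng.standard_normal(m), y0 + jit * rng.standard_normal(m))

    def walk(arm_axis, sign, d0, d1):
        m = max(int(round(abs(d1 - d0) / speed * fs)), 1)
        along = np.linspace(d0, d1, m)
        across = 0.3 * rng.standard_normal(m)
        emit(*axis_xy(arm_axis, sign, along, across))

    closed_axis = "y" if geometry.open_axis == "x" else "x"
    # initial center dwell, facing an open arm
    dwell(0.0, 0.0, rng.uniform(0.5, 1.0))
    while sum(a.size for a in xs) < n_total:
        total = sum(a.size for a in xs)
        frac = open_samples / max(total, 1)
        go_open = config.open_frac > 0 and frac < config.open_frac
        arm_axis = geometry.open_axis if go_open else closed_axis
        sign = 1 if rng.random() < 0.5 else -1
        depth = rng.uniform(0.4, 0.9) * geometry.arm_length + geometry.half_center
        walk(arm_axis, sign, geometry.half_center + 0.5, depth)
        base_dwell = rng.exponential(6.0)
        x0, y0 = _dwell_xy(geometry, arm_axis, sign, depth)
        dwell(x0, y0, base_dwell if go_open else max(base_dwell, 2.5))
        walk(arm_axis, sign, depth, geometry.half_center + 0.5)
        dwell(0.0, 0.0, rng.uniform(0.4, 1.2))
    x = np.concatenate(xs)[:n_total]
    y = np.concatenate(ys)[:n_total]
    time = np.arange(n_total) / fs
    return BehaviorTrack(time=time, x=x, y=y)


def _dwell_xy(geometry, arm_axis, sign, depth):
    if arm_axis == geometry.open_axis:
        return sign * depth, 0.0
    return 0.0, sign * depth


def generate_session(config: SynthConfig,
                     geometry: beh.EPMGeometry = beh.EPMGeometry(),
                     genotype: str = "wt", animal_id: str = "") -> Session:
    """One full synthetic session: trajectory, approach events, LFP pair.

    Closed-arm -> center entries are detected on the generated track and
    used as the modulation events for the LFP generator, so the behavioral
    and electrophysiological ground truths agree.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_track, rng_lfp = (np.random.default_rng(s) for s in ss.spawn(2))
    track = generate_epm_session(config, geometry, rng=rng_track)
    labels = beh.classify_zones(track, geometry)
    smoothed = beh.smooth_labels(labels, track.fs)
    runs = beh.detect_runs(smoothed, track, geometry)
    events = np.array([r.t_entry for r in runs])
    rec, truth = generate_lfp_pair(config, event_times=events,
                                   genotype=genotype, rng=rng_lfp)
    return Session(recording=rec, track=track, truth=truth,
                   animal_id=animal_id, genotype=genotype)


def generate_cohort(n_wt: int, n_het: int, base: SynthConfig,
                    seed: int | None = None,
                    geometry: beh.EPMGeometry = beh.EPMGeometry(),
                    het_coupling_scale: float = 0.6,
                    het_open_frac: float | None = None) -> list[Session]:
    """A cohort of WT and Het sessions with genotype-dependent structure.

    WT sessions keep ``base.approach_gain`` (> 1: couplings ramp at center
    approaches); Het sessions get ``approach_gain = 1`` (flat), a global
    coupling reduction (``het_coupling_scale``) and a higher open-arm
    occupancy target.  Per-session seeds derive deterministically from
    ``seed`` (default: ``base.seed``).
    """
    if n_wt < 0 or n_het < 0 or n_wt + n_het < 1:
        raise ValueError("need at least one session")
    if het_open_frac is None:
        het_open_frac = min(2.0 * base.open_frac, 1.0)
    master = base.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_wt + n_het) % (2**31)
    sessions = []
    for i in range(n_wt + n_het):
        wt = i < n_wt
        cfg = dataclasses.replace(
            base,
            seed=int(child_seeds[i]),
            approach_gain=base.approach_gain if wt else 1.0,
            coupling_scale=base.coupling_scale if wt else het_coupling_scale * base.coupling_scale,
            open_frac=base.open_frac if wt else het_open_frac,
        )
        genotype = "wt" if wt else "het"
        animal_id = f"{genotype}{i if wt else i - n_wt:02d}"
        sessions.append(generate_session(cfg, geometry, genotype, animal_id))
    return sessions
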