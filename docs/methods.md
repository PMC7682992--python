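# Methods

This note records how each stage of the pipeline is computed, which knobs
matter, what the synthetic data do and do not emulate, and where the open
design choices were settled.

## Signals and features

**Filtering.** Band-pass filtering is FIR (Hamming window), with filter
length three periods of the band's low edge (forced odd for symmetry), the
convention used for these recordings.  The kernel is applied forward and
backward in one convolution with its autocorrelation, so the output is
exactly zero-phase with an |H|² magnitude response.  Half a filter length
is trimmed from each end before the Hilbert transform; the trimmed offset
is carried in the `AnalyticSignal` so windows can still be addressed in
absolute samples.  A consequence worth knowing: for the high bands the
3-period prescription gives short kernels (92 taps at 65 Hz low edge, i.e.
a transition band of tens of Hz), so high-band edges are soft.  This
attenuates measured phase–amplitude coupling below its ideal m/2 value on
amplitude-modulated signals (sidebands sit on the response shoulder); the
closed-form m/2 limit is met within 0.02 for modulation at low frequencies,
and all coupling comparisons in the package are made with the same filters
on both sides.

**Band catalogue.** Single-frequency measures use theta 4–12, beta 13–30,
low gamma 30–55, high gamma 65–100 Hz (power per region; WPLI and amplitude
covariation between regions).  Phase–amplitude coupling uses low bands
theta 2–6 and alpha 6–10 Hz against the three high bands, over all four
ordered region pairs — 24 cross-frequency features, 40 in total.  Note the
deliberate reuse of the name "theta" at 2–6 Hz in the coupling set; an
8 Hz rhythm is captured by the alpha 6–10 phase band.

**Estimators.** Band power integrates Welch's PSD (2 s nonoverlapping
segments — at least two theta cycles at 1 Hz-ish resolution; closed
interval [lo, hi]).  WPLI is the plain (non-debiased) ratio
|E Im S| / E |Im S| computed per sample from analytic signals, with the
cross-term ordered S = z_vHPC·conj(z_mPFC) so a positive imaginary mean
means the hippocampus leads; the debiased variant is available but off by
default.  The 0/0 case (no imaginary structure, e.g. exact zero lag)
returns 0: no measurable lagged synchrony.  Im S is evaluated as
A·A·sin(Δφ), which makes that convention exact rather than a rounding
accident.  Amplitude covariation is the Pearson correlation of the two
instantaneous amplitudes (0, flagged, if either is constant).  The
phase–amplitude modulation index is the amplitude-weighted mean resultant
length; an all-zero amplitude returns 0 with a warning.

**Windows.** Event-locked dynamics use 2.5 s windows centered (symmetric
leakage) on an 11-point grid from −7.5 to +7.5 s in 1.5 s steps around
each closed-arm → center entry; each run's grid is z-scored against its own
11 points.  Continuous feature time series reuse the same 2.5 s / 1.5 s
windowing across the whole session, so the decomposition stage and the
event-locked stage share one windowing convention.  Bulk (whole-session)
measures use all samples between the filter-edge trims; no
movement/immobility mask is applied by default, though callers can slice
signals before measuring.

## EPM scoring

The maze is two 30 × 5 cm open arms, two closed arms and a 5 × 5 cm center
(standard mouse dimensions; configurable).  Zones are assigned by dominant
coordinate, so out-of-bounds tracking points snap to the nearest zone and
are logged.  Entries are counted on dwell-smoothed labels (sub-0.5 s blips
merged into the preceding zone) to suppress tracker jitter at boundaries —
after smoothing, the entry count equals the number of maximal open-label
segments not starting the session.  An approach run requires at least 1.5 s
of closed-arm dwell before the center entry, so the pre-entry window
reflects closed-arm context; the run is "closed-center-open" when the next
non-center zone reached is an open arm.  The tracked point is taken as
given (single-point tracking; no nose/center-of-mass distinction).

## Network discovery

Features are z-scored per column (constant columns dropped with a warning)
and the number of significant components is the count of correlation-matrix
eigenvalues above the Marchenko–Pastur edge (1 + √(p/n))², the null edge
for standardized data (σ² = 1).  fastICA (logcosh contrast, symmetric
extraction, tol 1e-4) runs on that many components; weight vectors are
returned in feature space, unit-norm, sign-canonicalized (largest-magnitude
entry positive).  The symmetric fixed-point iteration can cycle without
converging when the weakest retained component is nearly Gaussian (its
eigenvalue sits at the MP edge), so non-convergence retries with a fresh
seed and then switches to one-unit (deflation) extraction, which is robust
in exactly that regime.

Pooled components are clustered by pairwise Pearson correlation of their
weight vectors.  Because ICA signs are arbitrary, correlations are
sign-aligned (|r| compared to the 0.7 threshold); the binarized matrix is a
graph whose connected components, when they span at least three animals,
become clusters.  The characteristic network is the renormalized mean of
sign-aligned members, and its activity time course is the dot product of
the characteristic weights with each session's z-scored features.

## Synthetic sessions

The generator emulates a 15-min EPM session recorded at 2000 Hz from two
channels.  Ingredients, per channel: unit-variance 1/f background
(spectral shaping, exponent 1, flattened below 0.5 Hz); a narrowband 8 Hz
theta rhythm — a cosine with Wiener phase drift (3.5 rad/√s, ≈ 2 Hz
linewidth: wide enough that independent channels' phase difference
decorrelates within seconds, narrow enough for a clean spectral peak) —
with vHPC amplitude at `theta_snr` (default 4) times the in-band background
RMS; and three constant-amplitude carriers at 20 / 42 / 80 Hz (2.5× the
in-band background RMS) whose shared envelope is 1 + m(t)·cos(vHPC theta
phase).  The mPFC theta is a coupling-weighted mixture of the shared theta
(delayed by the phase lag, default 0.5 rad, hippocampus leading) and an
independent theta process, keeping variance constant.

The two coupling traces — theta phase coupling c(t) and modulation depth
m(t) — are the latent "networks".  Each is baseline × gain(t) × (1 +
drift(t)), where gain ramps linearly from 3 s before each closed→center
entry to a peak at entry and decays over 1.5 s, with independent
exponential per-event amplitudes, and drift is sparse shot noise (Poisson
bursts smoothed over ~10 s, SD 0.45).  Two properties of this construction
are load-bearing for the discovery stage: the drifts are **bursty**
(near-Gaussian sources are unidentifiable for ICA) and the two traces are
**not copies** (they share event times but not amplitudes or drifts, so
per-animal ICA can separate them).  Wild-type sessions use approach gain
2.5; heterozygous sessions use gain 1 (flat) plus a global 0.6 coupling
reduction, carrying both the event-locked interaction and the baseline
group difference.  Baseline coupling defaults to 0.35 so that the mPFC
phase is only partially locked to the hippocampus — this is what makes the
planted network specifically a *hippocampal-phase* coupling network rather
than appearing equally in the mPFC-phase features.

The trajectory generator alternates arm visits with brief center dwells,
choosing the next arm class by bang-bang feedback on the running open-time
fraction (so the measured fraction converges to the target within a bout
length, ±0.05 over 15 min), with closed dwells floored at 2.5 s so
approach runs satisfy the closed-dwell requirement.  Het sessions target
twice the WT open fraction, mirroring reduced avoidance.

What the generator does **not** emulate: volume conduction, movement and
chewing artifacts, electrode drift, nonstationary theta frequency,
genotype differences in power, or any LFP–behavior coupling beyond the
approach ramps.  Passing round-trip tests therefore shows the estimators
and the discovery logic are correct on signals with this structure — not
that real recordings will be as clean.

## Feedforward-inhibition model

Two (optionally three) leaky integrate-and-fire cells with shared
constants: membrane τ 20 ms, threshold 1, rest/reset 0, refractory 2 ms,
dt 0.1 ms (all config-exposed; only the synaptic decay constants τ_E =
8 ms, τ_I = 20 ms and the input statistics are fixed by the study design).
Synapses are current-based exponential traces — each presynaptic spike
increments a trace decaying with τ_E (excitation) or τ_I (inhibition), and
dV/dt = −V/τ_m + Σ w·trace.  Within a time step cells update in causal
order ISI → FSIN → pyramidal.  Inputs are per-bin Bernoulli approximations
of Poisson processes (p = rate·dt, valid for p < 0.2): hippocampal rate
(R/2)(1 − cos 2πft) with R = 100 Hz, f = 8 Hz, phase starting at the rate
minimum; noise constant at 50 Hz.  Rates and correlations are averaged
over 1000 iterations of 1 s with fresh input realizations.

**Calibration** exploits monotonicity: the shared excitatory weight onto
the pyramidal cell is bisected to the no-inhibition target (~50 Hz); the
FSIN weight to ~20 Hz (the FSIN receives no inhibition in the base
circuit, so stages are independent); the inhibitory weight to the
with-inhibition target (~25 Hz).  Search evaluations share one seed so
each stage bisects a deterministic function; an optional verification
re-simulates at full iteration count and enforces ±10%.

**Correlations and SNR.** Input–output correlation is the Pearson
correlation of 10 ms binned spike counts (bin width resolves theta-cycle
structure while keeping counts non-sparse; config-exposed), computed per
iteration and averaged, skipping iterations with zero variance; SNR is the
ratio of the hippocampal to the noise correlation.  The drive sweep scales
both FSIN input weights together (hippocampal-only mode available) over a
default grid of 0–3× the calibrated point: the SNR optimum sits near
1.5–2×, and beyond ~3× the pyramidal cell is essentially silent (< 0.2 Hz)
so the correlation ratio stops being estimable.  The disinhibition variant
adds an interneuron-selective interneuron (inputs → ISI ⊣ FSIN) and reduces
exactly to the base model when its weights are zero.  The frequency sweep
repeats the calibrated-drive measurement with the hippocampal modulation
frequency replaced.

## Statistics

The rank-sum test reports the rank sum of the first sample and a two-sided
p.  Exact mode computes the full permutation null by dynamic programming
over the (doubled, so tie-averaged half-integer ranks become integers) rank
multiset — equivalent to enumerating all label assignments at any sample
size — with p = 2·min(tail probabilities) capped at 1.  Normal mode uses
the tie-corrected variance with a 0.5 continuity correction, which keeps it
within 0.01 of the exact p at 15 per group.

The timepoint × genotype interaction is tested by permutation at the
**animal** level: each animal contributes the mean over its runs of the
entry-minus-baseline contrast (baseline = average of the first and last
grid points by default; any timepoint subset can be the baseline), the
statistic is the genotype difference of animal means, and the null permutes
genotype labels across animals so runs never leave their animal —
preserving within-animal correlation, which run-level shuffling would
destroy.  Fewer than 100 distinct assignments triggers exact enumeration;
otherwise p = (1 + #{|T*| ≥ |T|}) / (n_perm + 1).  Type-I calibration with
induced within-animal correlation and power at the planted 1.5 z effect are
exercised in the test suite.  Linear mixed models are deliberately not
re-implemented; a tidy per-run table can be exported for external fitting.

## Problem sizes used in the checks

The cohort round-trip check runs 13 animals (7 WT / 6 Het) at the full
900 s session length — the discovery stage needs the ~600 windows a
15-min session provides for clean per-animal separation — processing
sessions one at a time, since a session's twelve band-limited analytic
signals are the memory-heavy intermediate.  Model sweeps in the test suite
use the full 1000-iteration protocol for the quantities compared against
the study's operating point and reduced iteration counts (150–300) for
monotonicity and reduction checks.  Null-distribution checks use 100
random matrices (component gate), and 1000 / 200 simulated cohorts for
type-I error / power of the permutation test.

## Known limitations

- The m/2 closed form for phase–amplitude coupling is attenuated by the
  short high-band filters (see above) and by background power sharing the
  amplitude band; comparisons should stay within one filter convention.
- WPLI on 2.5 s windows is noisy (a few tens of effective phase samples);
  the ground-truth recoverability of coupling traces is demonstrated at
  10 s windows.
- The component count inherits Tracy–Widom fluctuations at the MP edge:
  on pure noise a spurious component appears in a few percent of runs, and
  a borderline component makes symmetric fastICA slow to converge (hence
  the deflation fallback).
- The circuit model is a caricature: current-based synapses, no
  conductances, no dendrites, two or three cells; its claims are about the
  qualitative shape of rate and SNR curves, not biophysical magnitudes.
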