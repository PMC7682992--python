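# thetalink

Analysis of theta-frequency communication between the ventral hippocampus
(vHPC) and medial prefrontal cortex (mPFC) during elevated-plus-maze (EPM)
behavior, for systems neuroscientists working with paired LFP + tracking
recordings.  The package covers the full chain from raw two-channel voltage
traces to cohort-level statistics:

- **Spectral / synchrony / coupling features** — zero-phase FIR filtering,
  Hilbert analytic signals, Welch band power, the weighted phase-lag index
  (WPLI), amplitude covariation, and phase–amplitude coupling, over the
  standard band catalogue (40 features: 16 single-frequency + 24
  cross-frequency), in bulk and in 2.5 s windows stepped 1.5 s around
  behavioral events (±7.5 s, an 11-point grid).
- **EPM scoring** — zone labels, occupancy/entry/distance metrics, and
  detection of the closed-arm → center "approach" runs that anchor all
  event-locked analyses.
- **Data-driven network discovery** — per-animal PCA with the
  Marchenko–Pastur significance gate, fastICA, cross-animal clustering of
  component weight vectors (|r| > 0.7 graph components spanning ≥ 3
  animals), characteristic-network extraction and projection onto behavior.
- **Feedforward-inhibition model** — two leaky integrate-and-fire cells
  (pyramidal + fast-spiking interneuron) driven by a theta-modulated
  Poisson "hippocampal" input and a constant-rate "noise" input, with
  calibration, drive sweeps, a disinhibition variant, and input-frequency
  sweeps.
- **Slice measures** — evoked-charge, paired-pulse ratio, spike latency and
  spike counts from intracellular traces.
- **Statistics** — exact/approximate Wilcoxon rank-sum and an animal-level
  permutation test for timepoint × genotype interactions.
- **Synthetic data** — a generator producing paired LFP + EPM trajectories
  with known ground-truth coupling, so every stage is testable end to end.

## Core quantities

For band-limited analytic signals `z_x = A_x e^{iφ_x}` the per-sample
cross-term is `S = z_vHPC · conj(z_mPFC)` and

```
WPLI = |E[Im S]| / E[|Im S|]          ∈ [0, 1]
```

(zero-lag coupling has Im S ≡ 0 and returns 0).  A positive `E[Im S]` means
the hippocampus leads.  Phase–amplitude coupling is the amplitude-weighted
mean resultant of the low-band phase:

```
MI = |Σ_t A_hi(t) e^{iφ_lo(t)}| / Σ_t A_hi(t)   ∈ [0, 1]
```

For `A_hi = 1 + m·cos φ_lo` with uniform phase coverage, `MI → m/2`.  The
component-count gate keeps eigenvalues of the feature correlation matrix
above the Marchenko–Pastur edge `λ_max = (1 + √(p/n))²`.

The circuit model integrates `dV/dt = −V/τ_m + I(t)` with current-based
exponential synapses (τ_E = 8 ms, τ_I = 20 ms), hippocampal input rate
`r(t) = 50·(1 − cos 2π·8t)` Hz and 50 Hz noise; the model SNR is
`corr(pyr, hpc) / corr(pyr, noise)` on 10 ms binned spike counts.

## Worked example

```bash
python examples/feedforward_model.py
```

prints (abbreviated):

```
calibrated rates: FSIN 19.8 Hz, pyramidal 25.0 Hz with inhibition, 49.4 Hz without

 drive  rate_pyr  rate_fsin  corr_hpc  corr_noise   snr
   0.0    50.127      0.000     0.485       0.362 1.339
   1.0    24.723     20.573     0.443       0.307 1.445
   1.5     7.563     39.710     0.335       0.196 1.709
   3.0     0.177     86.383     0.175       0.120 1.460

SNR vs hippocampal modulation frequency:
 freq   snr
  1.0 0.976
  8.0 1.445
 40.0 1.101
```

Reading: with the circuit calibrated so the interneuron fires ~20 Hz and
the pyramidal cell ~25 Hz, sweeping the interneuron's excitatory drive
shows the signal-to-noise of hippocampal transmission rising to an interior
optimum (~1.5× the calibrated drive) before collapsing — too little
feedforward inhibition fails to filter noise, too much silences the output.
The enhancement is specific to theta-range (8 Hz) input modulation.  The
other scripts in `examples/` walk the remaining capabilities (session
generation, LFP features, EPM scoring, network discovery, evoked traces,
group statistics), each printing its numbers with a line on what they mean.

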