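"""Band-limited synchrony and coupling measures on a synthetic pair.

Computes the three families of two-channel measures — band power, weighted
phase-lag index (WPLI), amplitude covariation — and the phase-amplitude
modulation index, on a recording whose ground truth is known, so each
printed number can be read against what was put in.
"""

import numpy as np

from thetalink import features as F
from thetalink import synth

cfg = synth.SynthConfig(duration=120.0, coupling_strength=0.8, phase_lag=0.5,
                        cfc_depth=0.6, approach_gain=1.0, slow_mod_sd=0.0,
                        seed=2)
rec, truth = synth.generate_lfp_pair(cfg)

theta = F.BandSpec("Theta", 4, 12)
alpha = F.BandSpec("Alpha", 6, 10)
high_gamma = F.BandSpec("HighGamma", 65, 100)

print(f"theta band power  vHPC {F.band_power(rec.hpc, theta, rec.fs):.3f}  "
      f"mPFC {F.band_power(rec.pfc, theta, rec.fs):.3f}")
w = F.wpli(rec.hpc, rec.pfc, theta, rec.fs)
print(f"theta WPLI = {w:.3f}  (generator coupling 0.8 with 0.5 rad lag)")
print(f"lead/lag: {F.lead_lag_sign(rec.hpc, rec.pfc, theta, rec.fs)} "
      f"(positive imaginary cross-term = hippocampus leads)")
mi = F.cfc(rec.hpc, alpha, rec.hpc, high_gamma, rec.fs)
print(f"theta-phase -> high-gamma-amplitude MI = {mi:.3f} "
      f"(modulation depth 0.6 -> ideal m/2 = 0.30; band-filter attenuation "
      f"lowers the measured value)")
ac = F.amplitude_covariation(rec.hpc, rec.pfc, high_gamma, rec.fs)
print(f"high-gamma amplitude covariation = {ac:.3f} "
      f"(both channels share the theta-locked envelope)")
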