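"""Discover a conserved LFP network across a small synthetic cohort.

Runs the data-driven stage on four animals (shortened sessions to keep the
example quick): per-animal windowed features, Marchenko-Pastur
dimensionality, fastICA, cross-animal clustering at |r| > 0.7, and the
projection of the characteristic network onto event-locked behavior.
"""

import numpy as np

from thetalink import networks as N
from thetalink import pipeline as P
from thetalink import synth

base = synth.SynthConfig(duration=420.0, seed=4, open_frac=0.15)
cohort = synth.generate_cohort(4, 0, base, seed=4)

feats = []
for sess in cohort:
    sf = P.analyze_session(sess)
    k = N.count_significant_components(sf.feature_matrix)
    print(f"{sf.animal_id}: {sf.feature_matrix.n} windows, "
          f"{k} significant components, {sf.event_times.size} approach runs")
    feats.append(sf)

clusters = N.cluster_many([sf.feature_matrix for sf in feats], seed=7,
                          min_animals=3)
print(f"\nclusters conserved across >= 3 animals: {len(clusters)}")
for c in clusters:
    top = [c.columns[j] for j in np.argsort(np.abs(c.characteristic))[::-1][:5]]
    print(f"  {len(c.members)} members from {len(c.animals)} animals; "
          f"top features: {', '.join(top)}")
    profile = np.mean([sf.project_events(c.characteristic).mean(axis=0)
                       for sf in feats], axis=0)
    print(f"  event-locked activity (z, -7.5 .. +7.5 s): "
          f"{np.array2string(profile, precision=2)}")
# In wild-type animals the coupling-driven clusters rise as the animal
# approaches the center (peak at the middle grid point, t = 0).
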