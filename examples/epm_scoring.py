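"""Score an elevated-plus-maze trajectory: occupancy, entries, approaches.

Generates a 15-minute trajectory with a 20% open-arm occupancy target and
prints the standard anxiety metrics plus the closed-arm -> center approach
events that anchor the event-locked LFP analyses.
"""

from thetalink import behavior as beh
from thetalink import synth

cfg = synth.SynthConfig(duration=900.0, open_frac=0.20, seed=3)
track = synth.generate_epm_session(cfg)

labels = beh.smooth_labels(beh.classify_zones(track), track.fs)
metrics = beh.occupancy_metrics(labels, track)
runs = beh.detect_runs(labels, track)

print(f"open/closed time ratio : {metrics['open_closed_ratio']:.2f}")
print(f"open time              : {metrics['open_time']:.0f} s "
      f"(target fraction 0.20 of 900 s)")
print(f"center time            : {metrics['center_time']:.0f} s")
print(f"distance traveled      : {metrics['distance']:.0f} cm")
print(f"open-arm entries       : {metrics['open_entries']}, "
      f"mean visit {metrics['mean_open_visit']:.1f} s")
n_open = sum(r.type == "closed_center_open" for r in runs)
print(f"approach runs          : {len(runs)} closed->center "
      f"({n_open} continue into an open arm)")
# Anxious animals keep the ratio low; the approach count is what matters
# for event-locked averaging (tens per session).
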