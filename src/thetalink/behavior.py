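"""Elevated-plus-maze scoring: zone labels, occupancy metrics, run events.

The maze is a plus of two open arms, two closed arms and a central square.
Everything downstream of the tracker is scored here: per-sample zone labels,
the standard anxiety metrics (open/closed time ratio, entries, visit
durations, distance), and the closed-arm -> center "approach" events that
anchor the event-locked LFP analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .features import DynamicWindowSpec, windowed_features, zscore_event_dynamics
from .session import BehaviorTrack, PairedRecording

logger = logging.getLogger(__name__)

__all__ = [
    "EPMGeometry",
    "RunEvent",
    "classify_zones",
    "smooth_labels",
    "occupancy_metrics",
    "detect_runs",
    "align_to_events",
]

#: zone label values
OPEN, CLOSED, CENTER = "open", "closed", "center"


@dataclass(frozen=True)
class EPMGeometry:
    """Maze dimensions in cm.  Open arms run along ``open_axis``.

    Defaults are standard mouse EPM dimensions: 30 x 5 cm arms around a
    5 x 5 cm center square.
    """

    arm_length: float = 30.0
    arm_width: float = 5.0
    center_size: float = 5.0
    open_axis: str = "x"

    def __post_init__(self) -> None:
        if self.open_axis not in ("x", "y"):
            raise ValueError("open_axis must be 'x' or 'y'")
        if min(self.arm_length, self.arm_width, self.center_size) <= 0:
            raise ValueError("all dimensions must be positive")

    @property
    def half_center(self) -> float:
        return self.center_size / 2.0

    def zone_and_arm(self, x: np.ndarray, y: np.ndarray):
        """Vectorized zone label + signed arm id per sample.

        Arm ids: +1 / -1 for the positive / negative arm on each axis, 0 in
        the center.  Out-of-bounds points are snapped to the nearest zone by
        dominant coordinate.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        along_open, across = (x, y) if self.open_axis == "x" else (y, x)
        hc = self.half_center
        in_center = (np.abs(x) <= hc) & (np.abs(y) <= hc)
        # dominant axis decides the arm for everything outside the center
        open_side = np.abs(along_open) > np.abs(across)
        zones = np.where(in_center, CENTER, np.where(open_side, OPEN, CLOSED))
        arm = np.where(in_center, 0,
                       np.where(open_side, np.sign(along_open), np.sign(across)))
        return zones.astype(object), arm.astype(int)


@dataclass(frozen=True)
class RunEvent:
    """A closed-arm approach to the center.

    ``type`` is ``closed_center_open`` when the next non-center zone after
    entry is an open arm, else ``closed_center``.  ``t_entry`` is the time
    of the first center sample.
    """

    type: str
    t_entry: float
    source_arm: int
    destination: str


def classify_zones(track: BehaviorTrack, geometry: EPMGeometry = EPMGeometry()) -> np.ndarray:
    """Per-sample zone labels in {open, closed, center}; also stored on the track."""
    if track.time.size == 0:
        raise ValueError("empty track")
    bound = geometry.half_center + geometry.arm_length
    oob = (np.abs(track.x) > bound) | (np.abs(track.y) > bound)
    if np.any(oob):
        logger.warning("%d samples out of maze bounds; snapped to nearest zone", oob.sum())
    zones, _ = geometry.zone_and_arm(track.x, track.y)
    track.zones = zones
    return zones


def _segments(labels: np.ndarray):
    """Maximal constant-label runs as (start, stop_exclusive, label)."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    return [(int(a), int(b), labels[a]) for a, b in zip(starts, stops)]


def smooth_labels(labels: np.ndarray, fs: float, min_dwell: float = 0.5) -> np.ndarray:
    """Suppress sub-``min_dwell`` zone blips (tracking jitter at boundaries).

    Segments shorter than ``min_dwell`` are merged into the preceding stable
    zone, so an entry only counts once the animal dwells.
    """
    labels = np.asarray(labels, dtype=object).copy()
    min_n = int(round(min_dwell * fs))
    segs = _segments(labels)
    for k, (a, b, lab) in enumerate(segs):
        if b - a < min_n and k > 0:
            labels[a:b] = labels[a - 1]  # previous segment may itself have been merged
    return labels


def occupancy_metrics(labels: np.ndarray, track: BehaviorTrack,
                      min_dwell: float = 0.5) -> dict:
    """Standard EPM metrics from a labeled track.

    Returns open/closed time ratio, open and center time (s), path length
    (cm), open-arm entry count and mean open-visit duration (s).  Entries
    are counted on dwell-smoothed labels to suppress jitter re-entries.
    """
    labels = np.asarray(labels, dtype=object)
    fs = track.fs
    dt = 1.0 / fs
    t_open = float(np.sum(labels == OPEN) * dt)
    t_closed = float(np.sum(labels == CLOSED) * dt)
    t_center = float(np.sum(labels == CENTER) * dt)
    if t_closed == 0:
        warnings.warn("zero closed-arm time: open/closed ratio undefined")
        ratio = np.nan
    else:
        ratio = t_open / t_closed
    dist = float(np.sum(np.hypot(np.diff(track.x), np.diff(track.y))))
    smoothed = smooth_labels(labels, fs, min_dwell)
    open_segs = [(a, b) for a, b, lab in _segments(smoothed) if lab == OPEN]
    # an opening segment at sample 0 is occupancy, not an entry
    entries = [(a, b) for a, b in open_segs if a > 0]
    durations = [(b - a) * dt for a, b in entries]
    return {
        "open_closed_ratio": ratio,
        "open_time": t_open,
        "closed_time": t_closed,
        "center_time": t_center,
        "distance": dist,
        "open_entries": len(entries),
        "mean_open_visit": float(np.mean(durations)) if durations else 0.0,
    }


def detect_runs(labels: np.ndarray, track: BehaviorTrack,
                geometry: EPMGeometry = EPMGeometry(),
                min_closed_dwell: float = 1.5) -> list[RunEvent]:
    """Closed-arm approaches to the center.

    An event fires at the first center sample following at least
    ``min_closed_dwell`` s spent in a closed arm.  Its type is
    ``closed_center_open`` iff the next non-center zone reached is open.
    """
    labels = np.asarray(labels, dtype=object)
    fs = track.fs
    _, arms = geometry.zone_and_arm(track.x, track.y)
    segs = _segments(labels)
    events: list[RunEvent] = []
    min_n = int(round(min_closed_dwell * fs))
    for k, (a, b, lab) in enumerate(segs):
        if lab != CENTER or k == 0:
            continue
        pa, pb, plab = segs[k - 1]
        if plab != CLOSED or (pb - pa) < min_n:
            continue
        dest = next((l for _, _, l in segs[k + 1:] if l != CENTER), None)
        run_type = "closed_center_open" if dest == OPEN else "closed_center"
        events.append(RunEvent(
            type=run_type,
            t_entry=float(track.time[a]),
            source_arm=int(arms[pb - 1]),
            destination=dest if dest is not None else "none",
        ))
    return events


def align_to_events(rec: PairedRecording, runs: list[RunEvent],
                    spec: DynamicWindowSpec = DynamicWindowSpec(),
                    analytics=None, run_type: str | None = None):
    """Event-locked, z-scored feature grids for a session's approach runs.

    Each run yields an 11-point grid per feature (t=0 at center entry),
    z-scored within run; runs too close to the session edges are dropped by
    the windowing layer and logged.  Returns (kept_times, zscored_grids)
    with grids of shape (n_runs, 11, 40).
    """
    if run_type is not None:
        runs = [r for r in runs if r.type == run_type]
    if not runs:
        raise ValueError("no usable runs")
    times = np.array([r.t_entry for r in runs])
    kept, grids = windowed_features(rec, times, spec, analytics=analytics)
    return kept, zscore_event_dynamics(grids)
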