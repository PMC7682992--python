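"""Session containers and on-disk formats.

A session pairs a two-channel LFP recording (ventral hippocampus and medial
prefrontal cortex) with a position-tracking table from an elevated plus maze
trial.  Sessions round-trip through HDF5 (groups ``/lfp/hpc``, ``/lfp/pfc``,
``/behavior/track``, ``/ground_truth``); tracking alone round-trips through a
plain CSV with columns ``time_s, x_cm, y_cm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PairedRecording",
    "BehaviorTrack",
    "GroundTruth",
    "Session",
    "save_session",
    "load_session",
    "read_track_csv",
    "write_track_csv",
]


@dataclass
class PairedRecording:
    """Synchronized vHPC + mPFC voltage series.

    Attributes
    ----------
    hpc, pfc : ndarray
        Equal-length voltage traces (arbitrary units).
    fs : float
        Sampling rate in samples/s.
    meta : dict
        Free-form session metadata (animal id, genotype, ...).
    """

    hpc: np.ndarray
    pfc: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hpc = np.asarray(self.hpc, dtype=float)
        self.pfc = np.asarray(self.pfc, dtype=float)
        if self.hpc.shape != self.pfc.shape or self.hpc.ndim != 1:
            raise ValueError("hpc and pfc must be equal-length 1-D arrays")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be a positive finite number")

    @property
    def n_samples(self) -> int:
        return self.hpc.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class BehaviorTrack:
    """Timestamped 2-D positions (cm) on the maze, optionally zone-labeled."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    zones: np.ndarray | None = None  # per-sample labels, filled by behavior.classify_zones

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.shape == self.x.shape == self.y.shape):
            raise ValueError("time, x, y must share one shape")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def fs(self) -> float:
        if self.time.size < 2:
            raise ValueError("need >= 2 samples to infer a rate")
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic session.

    ``coupling`` and ``cfc_depth`` are per-LFP-sample traces of the shared
    theta fraction and the phase-amplitude modulation depth; ``event_times``
    are the closed-arm -> center entry times (s) the generator modulated
    around.
    """

    coupling: np.ndarray
    cfc_depth: np.ndarray
    event_times: np.ndarray
    genotype: str

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.cfc_depth = np.asarray(self.cfc_depth, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)


@dataclass
class Session:
    """One animal-session: LFP pair + EPM track (+ truth when synthetic)."""

    recording: PairedRecording
    track: BehaviorTrack
    truth: GroundTruth | None = None
    animal_id: str = ""
    genotype: str = ""


def save_session(path: str | Path, session: Session) -> None:
    """Write a session to HDF5 (layout: /lfp/{hpc,pfc}, /behavior/track, /ground_truth)."""
    rec, track = session.recording, session.track
    with h5py.File(path, "w") as f:
        lfp = f.create_group("lfp")
        lfp.create_dataset("hpc", data=rec.hpc, compression="gzip")
        lfp.create_dataset("pfc", data=rec.pfc, compression="gzip")
        lfp.attrs["fs"] = rec.fs
        beh = f.create_group("behavior")
        beh.create_dataset(
            "track", data=np.column_stack([track.time, track.x, track.y])
        )
        f.attrs["animal_id"] = session.animal_id
        f.attrs["genotype"] = session.genotype
        if session.truth is not None:
            gt = f.create_group("ground_truth")
            gt.create_dataset("coupling", data=session.truth.coupling, compression="gzip")
            gt.create_dataset("cfc_depth", data=session.truth.cfc_depth, compression="gzip")
            gt.create_dataset("event_times", data=session.truth.event_times)
            gt.attrs["genotype"] = session.truth.genotype


def load_session(path: str | Path) -> Session:
    """Read a session written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        rec = PairedRecording(
            hpc=f["lfp/hpc"][:], pfc=f["lfp/pfc"][:], fs=float(f["lfp"].attrs["fs"])
        )
        t, x, y = f["behavior/track"][:].T
        track = BehaviorTrack(time=t, x=x, y=y)
        truth = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            truth = GroundTruth(
                coupling=gt["coupling"][:],
                cfc_depth=gt["cfc_depth"][:],
                event_times=gt["event_times"][:],
                genotype=str(gt.attrs.get("genotype", "")),
            )
        return Session(
            recording=rec,
            track=track,
            truth=truth,
            animal_id=str(f.attrs.get("animal_id", "")),
            genotype=str(f.attrs.get("genotype", "")),
        )


def read_track_csv(path: str | Path) -> BehaviorTrack:
    """Read an ANY-maze-style export: columns time_s, x_cm, y_cm."""
    df = pd.read_csv(path)
    return BehaviorTrack(
        time=df["time_s"].to_numpy(), x=df["x_cm"].to_numpy(), y=df["y_cm"].to_numpy()
    )


def write_track_csv(path: str | Path, track: BehaviorTrack) -> None:
    pd.DataFrame({"time_s": track.time, "x_cm": track.x, "y_cm": track.y}).to_csv(
        path, index=False
    )
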