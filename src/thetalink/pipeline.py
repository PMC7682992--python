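"""End-to-end session analysis: features -> events -> networks -> stats.

Glues the stages together the way a cohort analysis runs them: compute the
windowed 40-feature table and event-locked grids for each session (one
session at a time — the band-limited analytic signals of a 15-min recording
are large, so nothing heavy is retained), pool the per-animal feature
matrices for network discovery, project a characteristic network back onto
each session's standardized features, and hand the aligned run grids to the
interaction test.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass

import numpy as np

from . import behavior as beh
from . import features as F
from . import networks as N
from . import stats as S
from .session import Session

__all__ = ["SessionFeatures", "analyze_session", "aligned_network_runs"]


@dataclass
class SessionFeatures:
    """Windowed features and event grids for one session (lightweight)."""

    animal_id: str
    genotype: str
    window_times: np.ndarray          # centers of the continuous windows, s
    values: np.ndarray                # (n_windows, 40) raw feature values
    feature_matrix: N.FeatureMatrix   # standardized, for decomposition
    event_times: np.ndarray           # kept closed->center entries, s
    event_grids: np.ndarray           # (n_events, 11, 40) raw feature grids
    feature_mean: np.ndarray          # per-feature session mean / SD used to
    feature_sd: np.ndarray            # standardize event grids for projection

    def project_events(self, weights: np.ndarray) -> np.ndarray:
        """Within-run z-scored network activity on the event grids.

        Event-grid features are standardized against the session-wide
        feature distribution, projected onto ``weights``, then z-scored
        across each run's 11 grid points.
        """
        sd = np.where(self.feature_sd == 0, 1.0, self.feature_sd)
        z = (self.event_grids - self.feature_mean) / sd
        return F.zscore_event_dynamics(N.project_ic(weights, z))


def analyze_session(session: Session,
                    window_spec: F.DynamicWindowSpec = F.DynamicWindowSpec(),
                    run_type: str | None = None,
                    min_closed_dwell: float = 1.5) -> SessionFeatures:
    """Full single-session feature extraction.

    Detects closed-arm -> center approach runs on the track (optionally
    restricted to ``run_type``), computes the continuous windowed feature
    table and the per-run event-locked grids, and discards the heavy
    intermediate signals before returning.
    """
    rec = session.recording
    track = session.track
    labels = beh.smooth_labels(beh.classify_zones(track), track.fs)
    runs = beh.detect_runs(labels, track, min_closed_dwell=min_closed_dwell)
    if run_type is not None:
        runs = [r for r in runs if r.type == run_type]
    analytics = F.session_analytics(rec)
    times, values = F.compute_feature_table(rec, analytics=analytics)
    event_times = np.array([r.t_entry for r in runs])
    kept, grids = F.windowed_features(rec, event_times, window_spec,
                                      analytics=analytics)
    fm = N.build_feature_matrix(values, animal_id=session.animal_id)
    out = SessionFeatures(
        animal_id=session.animal_id,
        genotype=session.genotype,
        window_times=times,
        values=values,
        feature_matrix=fm,
        event_times=kept,
        event_grids=grids,
        feature_mean=values.mean(axis=0),
        feature_sd=values.std(axis=0),
    )
    del analytics
    gc.collect()
    return out


def aligned_network_runs(session_features: list[SessionFeatures],
                         weights: np.ndarray) -> S.AlignedRuns:
    """Pool every session's projected, z-scored run grids for the
    genotype x timepoint interaction test."""
    grids, animals, genotypes = [], [], {}
    for sf in session_features:
        act = sf.project_events(weights)
        grids.append(act)
        animals += [sf.animal_id] * act.shape[0]
        genotypes[sf.animal_id] = sf.genotype
    return S.AlignedRuns(np.vstack(grids), np.array(animals), genotypes)
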