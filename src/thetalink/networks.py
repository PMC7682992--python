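"""Data-driven network discovery across animals.

Per animal, the 40-feature windowed time series is standardized and its
dimensionality estimated from the correlation-matrix spectrum against the
Marchenko-Pastur upper edge (1 + sqrt(p/n))^2; fastICA then separates that
many components, each summarized as a unit-norm weight vector over the 40
features.  Components are pooled across animals, pairwise-correlated
(sign-aligned, since ICA signs are arbitrary), thresholded at |r| > 0.7 and
clustered by graph connectivity; clusters spanning at least three animals
yield a characteristic (member-averaged) weight vector whose projection
onto any session's standardized features gives a network-activity time
course.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ICWeights",
    "ICCluster",
    "build_feature_matrix",
    "marchenko_pastur_edge",
    "count_significant_components",
    "run_ica",
    "cluster_ics",
    "cluster_many",
    "project_ic",
    "save_clusters_json",
    "load_clusters_json",
]


@dataclass
class FeatureMatrix:
    """Standardized windowed features for one animal.

    ``values`` is (n_windows, n_features), z-scored per column; ``dropped``
    records constant columns that were removed.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    animal_id: str = ""
    dropped: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class ICWeights:
    """One independent component: unit-norm weights over the features.

    Sign is canonicalized so the largest-magnitude entry is positive.
    """

    animal_id: str
    weights: np.ndarray
    columns: tuple[str, ...]


@dataclass
class ICCluster:
    """A cross-animal cluster of similar ICs and its characteristic IC."""

    members: list[ICWeights]
    characteristic: np.ndarray
    columns: tuple[str, ...] = field(default_factory=tuple)

    @property
    def animals(self) -> set[str]:
        return {m.animal_id for m in self.members}


def _canonical(w: np.ndarray) -> np.ndarray:
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def build_feature_matrix(values, columns=FEATURE_NAMES, animal_id: str = "") -> FeatureMatrix:
    """Standardize a (windows x features) table for decomposition.

    Rows with non-finite entries and constant columns are dropped (and
    logged); remaining columns are z-scored to mean 0, SD 1.
    """
    if isinstance(values, pd.DataFrame):
        columns = tuple(values.columns)
        values = values.to_numpy(float)
    X = np.asarray(values, float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D windows x features array")
    if len(columns) != X.shape[1]:
        raise ValueError("column names do not match matrix width")
    good_rows = np.all(np.isfinite(X), axis=1)
    if not good_rows.all():
        logger.warning("dropping %d windows with undefined values", (~good_rows).sum())
        X = X[good_rows]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # tolerance absorbs accumulated rounding in the column reduction
    keep = sd > 1e-10 * np.maximum(1.0, np.abs(mu))
    dropped = tuple(c for c, k in zip(columns, keep) if not k)
    if dropped:
        warnings.warn(f"dropping constant feature column(s): {dropped}")
        X = X[:, keep]
        sd = sd[keep]
    cols = tuple(c for c, k in zip(columns, keep) if k)
    Z = (X - X.mean(axis=0)) / sd
    return FeatureMatrix(values=Z, columns=cols, animal_id=animal_id, dropped=dropped)


def marchenko_pastur_edge(n: int, p: int) -> float:
    """Upper eigenvalue edge (1 + sqrt(p/n))^2 of the null correlation spectrum."""
    return (1.0 + np.sqrt(p / n)) ** 2


def count_significant_components(fm: FeatureMatrix) -> int:
    """Eigenvalues of the feature correlation matrix above the MP edge."""
    n, p = fm.n, fm.p
    if n < 2:
        raise ValueError("need at least 2 windows")
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: Marchenko-Pastur threshold is unreliable")
    eig = np.linalg.eigvalsh(np.corrcoef(fm.values, rowvar=False))
    return int(np.sum(eig > marchenko_pastur_edge(n, p)))


def run_ica(fm: FeatureMatrix, k: int, seed: int = 0, max_retries: int = 5) -> list[ICWeights]:
    """fastICA on the top-k PCA subspace; weights back in feature space.

    Uses the logcosh contrast with parallel (symmetric) extraction at
    tolerance 1e-4.  The symmetric fixed-point iteration can cycle without
    converging when the weakest retained component sits near the
    Marchenko-Pastur edge (nearly Gaussian), so retries escalate: a fresh
    seed with more iterations first, then one-unit (deflation) extraction,
    which is robust in exactly that regime.
    """
    if not 1 <= k <= fm.p:
        raise ValueError(f"k must be in [1, {fm.p}]")
    last_err: Exception | None = None
    schedule = [("parallel", 1e-4, 1000), ("parallel", 1e-4, 2000),
                ("deflation", 1e-4, 2000), ("deflation", 1e-4, 4000),
                ("deflation", 1e-3, 8000)]
    for attempt in range(max_retries):
        algorithm, tol, max_iter = schedule[min(attempt, len(schedule) - 1)]
        ica = FastICA(n_components=k, fun="logcosh", algorithm=algorithm,
                      whiten="unit-variance", tol=tol, max_iter=max_iter,
                      random_state=seed + attempt)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica.fit(fm.values)
            except ConvergenceWarning as err:  # retry with a fresh seed
                last_err = err
                logger.warning("fastICA did not converge (attempt %d); retrying", attempt + 1)
                continue
        W = ica.components_  # rows map standardized features -> sources
        return [ICWeights(animal_id=fm.animal_id, weights=_canonical(w),
                          columns=fm.columns) for w in W]
    raise RuntimeError(
        f"fastICA failed to converge after {max_retries} seeds "
        f"(n={fm.n}, p={fm.p}, k={k}): {last_err}")


def cluster_ics(ics: list[ICWeights], r_threshold: float = 0.7,
                min_animals: int = 3) -> list[ICCluster]:
    """Cluster pooled ICs by thresholded weight-vector correlation.

    Pairwise Pearson correlations are sign-aligned (|r| compared against
    the threshold), the binarized matrix is treated as a graph, and each
    connected component spanning >= ``min_animals`` distinct animals
    becomes a cluster.  The characteristic IC is the mean of the members
    after aligning each member's sign to the first, renormalized.
    """
    if not ics:
        return []
    W = np.stack([ic.weights for ic in ics])
    R = np.corrcoef(W)
    adj = (np.abs(R) > r_threshold) & ~np.eye(len(ics), dtype=bool)
    # isolated ICs (no partner above threshold) cannot seed a cluster
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue
        members = [ics[i] for i in idx]
        if len({m.animal_id for m in members}) < min_animals:
            continue
        ref = members[0].weights
        aligned = np.stack([m.weights * np.sign(m.weights @ ref or 1.0) for m in members])
        clusters.append(ICCluster(members=members,
                                  characteristic=_canonical(aligned.mean(axis=0)),
                                  columns=members[0].columns))
    return clusters


def cluster_many(feature_matrices: list[FeatureMatrix], seed: int = 0,
                 r_threshold: float = 0.7, min_animals: int = 3) -> list[ICCluster]:
    """Full pipeline: per-animal dimensionality + ICA, then pooled clustering."""
    ics: list[ICWeights] = []
    for i, fm in enumerate(feature_matrices):
        k = count_significant_components(fm)
        if k == 0:
            logger.info("animal %s: no significant components", fm.animal_id)
            continue
        ics.extend(run_ica(fm, k, seed=seed + 1000 * i))
    return cluster_ics(ics, r_threshold=r_threshold, min_animals=min_animals)


def save_clusters_json(path, clusters: list[ICCluster]) -> None:
    """Serialize clusters (members, animals, characteristic weights) to JSON."""
    import json

    payload = [
        {
            "animals": sorted(c.animals),
            "columns": list(c.columns),
            "characteristic": c.characteristic.tolist(),
            "members": [
                {"animal_id": m.animal_id, "weights": m.weights.tolist()}
                for m in c.members
            ],
        }
        for c in clusters
    ]
    with open(path, "w") as f:
        json.dump(payload, f)


def load_clusters_json(path) -> list[ICCluster]:
    """Inverse of :func:`save_clusters_json`."""
    import json

    with open(path) as f:
        payload = json.load(f)
    clusters = []
    for entry in payload:
        cols = tuple(entry["columns"])
        members = [ICWeights(m["animal_id"], np.asarray(m["weights"]), cols)
                   for m in entry["members"]]
        clusters.append(ICCluster(members=members,
                                  characteristic=np.asarray(entry["characteristic"]),
                                  columns=cols))
    return clusters


def project_ic(weights: np.ndarray, z_features: np.ndarray) -> np.ndarray:
    """Network activity: per-window dot product of weights with z-scored features."""
    weights = np.asarray(weights, float)
    Z = np.asarray(z_features, float)
    if Z.shape[-1] != weights.size:
        raise ValueError("feature dimension mismatch")
    return Z @ weights
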