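"""Group statistics: Wilcoxon rank-sum and an animal-level permutation test.

The rank-sum test is exposed with an exact small-sample mode (full
enumeration of label assignments) and a tie-corrected normal approximation.
The event-locked timepoint x genotype interaction is tested by permuting
genotype labels across *animals* — runs stay attached to their animal, so
within-animal correlation is preserved under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, NamedTuple

import numpy as np
from scipy import stats as sstats

__all__ = [
    "RankSumResult",
    "AlignedRuns",
    "rank_sum",
    "interaction_permutation_test",
]


class RankSumResult(NamedTuple):
    statistic: float  # rank sum of `a` (exact mode) or z (normal mode)
    pvalue: float


def rank_sum(a, b, mode: Literal["exact", "normal"] = "normal") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    ``exact`` computes the full permutation null of the rank sum (every
    assignment of the pooled values to the two groups, counted by dynamic
    programming over the rank multiset) and reports 2 * min(tail
    probabilities), capped at 1.  ``normal`` uses the z approximation with
    tie-corrected variance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    w_obs = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return RankSumResult(w_obs if mode == "exact" else 0.0, 1.0)
    if mode == "exact":
        lo, hi = _exact_tails(ranks, a.size, w_obs)
        return RankSumResult(w_obs, min(1.0, 2.0 * min(lo, hi)))
    if mode != "normal":
        raise ValueError("mode must be 'exact' or 'normal'")
    n1, n2 = a.size, b.size
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n - 1.0) * n)
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    # 0.5 continuity correction toward the mean (W is lattice-valued)
    delta = w_obs - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    return RankSumResult(float(z), float(2 * sstats.norm.sf(abs(z))))


def _exact_tails(ranks: np.ndarray, na: int, w_obs: float) -> tuple[float, float]:
    """P(W <= w_obs) and P(W >= w_obs) under the exact permutation null.

    Counts subsets of size ``na`` by dynamic programming over doubled ranks
    (tie-averaged ranks are half-integers, so doubling makes them exact
    integers); equivalent to enumerating all C(n, na) assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # counts[k][s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((na + 1, total + 1))
    counts[0, 0] = 1.0
    for r in r2:
        counts[1:, r:] += counts[:-1, : total + 1 - r]
    dist = counts[na]
    n_total = dist.sum()
    w2 = int(np.rint(2 * w_obs))
    lo = dist[: w2 + 1].sum() / n_total
    hi = dist[w2:].sum() / n_total
    return float(lo), float(hi)


@dataclass
class AlignedRuns:
    """Per-run event-locked grids with their animal and genotype maps.

    ``grids``: (n_runs, n_timepoints) z-scored values (one feature or one
    network projection); ``animals``: run -> animal id; ``genotypes``:
    animal id -> genotype label (exactly two labels).
    """

    grids: np.ndarray
    animals: np.ndarray
    genotypes: dict[str, str]

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, float)
        self.animals = np.asarray(self.animals)
        if self.grids.ndim != 2 or self.grids.shape[0] != self.animals.size:
            raise ValueError("grids must be (n_runs, n_timepoints) matching animals")
        missing = set(self.animals) - set(self.genotypes)
        if missing:
            raise ValueError(f"runs from unmapped animals: {missing}")


def _animal_contrasts(runs: AlignedRuns, entry_index: int,
                      baseline: str | list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal mean (entry - baseline) contrast and genotype array."""
    g = runs.grids
    if baseline == "ends":
        base = (g[:, 0] + g[:, -1]) / 2.0
    else:
        base = g[:, list(baseline)].mean(axis=1)
    contrast = g[:, entry_index] - base
    animal_ids = np.array(sorted(set(runs.animals.tolist())))
    per_animal = np.array([contrast[runs.animals == aid].mean() for aid in animal_ids])
    genos = np.array([runs.genotypes[aid] for aid in animal_ids])
    return per_animal, genos


def interaction_permutation_test(runs: AlignedRuns, entry_index: int,
                                 baseline: str | list[int] = "ends",
                                 n_perm: int = 2000, seed: int = 0) -> float:
    """Timepoint x genotype interaction by animal-level label permutation.

    The observed statistic is the genotype difference of the mean
    entry-minus-baseline contrast, where each animal contributes one value
    (the mean over its runs) and baseline defaults to the average of the
    first and last grid points.  The null distribution permutes genotype
    labels across animals; when fewer than 100 distinct assignments exist,
    all of them are enumerated instead of sampled.  Returns the two-sided
    permutation p-value.
    """
    per_animal, genos = _animal_contrasts(runs, entry_index, baseline)
    labels = sorted(set(genos.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two genotypes, got {labels}")
    is_a = genos == labels[0]
    n, na = genos.size, int(is_a.sum())
    if na < 2 or n - na < 2:
        raise ValueError("need >= 2 animals per genotype")

    def stat(mask: np.ndarray) -> float:
        return per_animal[mask].mean() - per_animal[~mask].mean()

    obs = abs(stat(is_a))
    from math import comb

    if comb(n, na) < 100:
        perms = np.zeros((comb(n, na), n), dtype=bool)
        for i, c in enumerate(combinations(range(n), na)):
            perms[i, list(c)] = True
        null = np.array([abs(stat(m)) for m in perms])
        return float(np.mean(null >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, na, replace=False)] = True
        if abs(stat(mask)) >= obs - 1e-12:
            count += 1
    return float((1 + count) / (n_perm + 1))
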