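"""Group comparisons: exact rank-sum and the animal-level permutation test.

Shows the two statistics the pipeline reports: a two-sided Wilcoxon
rank-sum for per-animal summary values, and the timepoint x genotype
interaction test that permutes genotype labels across animals (runs stay
with their animal, preserving within-animal correlation under the null).
"""

import numpy as np

from thetalink import stats as S

# per-animal open-arm time ratios for two genotypes
rng = np.random.default_rng(5)
wt_ratio = rng.normal(0.25, 0.08, 8)
het_ratio = rng.normal(0.45, 0.08, 9)
res = S.rank_sum(wt_ratio, het_ratio, mode="exact")
print(f"rank-sum (exact): W = {res.statistic:.0f}, p = {res.pvalue:.4f}")
res_n = S.rank_sum(wt_ratio, het_ratio, mode="normal")
print(f"rank-sum (normal approx): z = {res_n.statistic:.2f}, "
      f"p = {res_n.pvalue:.4f}")

# event-locked grids: WT animals carry a 1.2 z deflection at center entry
grids, animals, genos = [], [], {}
for i in range(13):
    wt = i < 7
    aid = f"m{i:02d}"
    genos[aid] = "wt" if wt else "het"
    g = rng.normal(0, 1, (20, 11)) + rng.normal(0, 0.5)
    if wt:
        g[:, 5] += 1.2
    grids.append(g)
    animals += [aid] * 20
runs = S.AlignedRuns(np.vstack(grids), np.array(animals), genos)
p = S.interaction_permutation_test(runs, entry_index=5, n_perm=2000, seed=0)
print(f"timepoint x genotype interaction (animal-level permutation): "
      f"p = {p:.4f}")
# Small p: the entry-locked deflection differs between genotypes beyond
# what shuffling whole animals between groups can produce.
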