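"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately avoid the library code paths they are used to check:
permutation nulls are enumerated exhaustively, with mid-p handling of the
discrete atom at the observed statistic (the standard way to compare a
continuous approximation against a discrete permutation distribution).
"""

from itertools import combinations

import numpy as np

from nanosip.population_stats import dunn_z_statistic, dunns_test, kruskal_wallis


def partitions(idx, sizes):
    """All assignments of the index set into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield [tuple(sorted(idx))]
        return
    for combo in combinations(sorted(idx), sizes[0]):
        for rest in partitions(set(idx) - set(combo), sizes[1:]):
            yield [combo] + rest


def kw_permutation_p(data):
    """Exhaustive mid-p permutation p-value for the Kruskal-Wallis H."""
    sizes = [len(d) for d in data]
    pooled = np.concatenate(data)
    h_obs, _ = kruskal_wallis({f"g{i}": d for i, d in enumerate(data)})
    gt = eq = total = 0
    for assign in partitions(set(range(len(pooled))), sizes):
        h, _ = kruskal_wallis({f"g{i}": pooled[list(a)] for i, a in enumerate(assign)})
        total += 1
        if h > h_obs + 1e-9:
            gt += 1
        elif h > h_obs - 1e-9:
            eq += 1
    return (gt + 0.5 * eq) / total


def dunn_permutation_p(data):
    """Per-group (normal-approx p, exhaustive mid-p) vs the last group."""
    sizes = [len(d) for d in data]
    pooled = np.concatenate(data)
    groups = {f"g{i}": d for i, d in enumerate(data)}
    ctrl = f"g{len(data) - 1}"
    res = dunns_test(groups, control=ctrl)
    zobs = {r.group: abs(r.z) for r in res}
    gt = {g: 0 for g in zobs}
    eq = {g: 0 for g in zobs}
    total = 0
    for assign in partitions(set(range(len(pooled))), sizes):
        gd = {f"g{i}": pooled[list(a)] for i, a in enumerate(assign)}
        total += 1
        for g in zobs:
            z = abs(dunn_z_statistic(gd, g, ctrl))
            if z > zobs[g] + 1e-9:
                gt[g] += 1
            elif z > zobs[g] - 1e-9:
                eq[g] += 1
    return {r.group: (r.p_raw, (gt[r.group] + 0.5 * eq[r.group]) / total) for r in res}


def ssd_shift_search(ref, img, max_shift):
    """Brute-force integer-shift search minimizing mean squared difference."""
    best, best_val = (0, 0), np.inf
    h, w = ref.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys_src = slice(max(-dy, 0), h + min(-dy, 0))
            xs_src = slice(max(-dx, 0), w + min(-dx, 0))
            diff = ref[ys, xs] - img[ys_src, xs_src]
            val = (diff**2).mean()
            if val < best_val - 1e-12:
                best, best_val = (dy, dx), val
    return best
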