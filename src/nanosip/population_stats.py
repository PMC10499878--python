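"""Inferential statistics on pooled per-cell measurements.

Groups (strain or treatment, pooled across biological replicates) are
compared with a Kruskal-Wallis test followed by Dunn's post-hoc test of
each group against a designated control, with Dunn-Sidak adjustment of the
per-comparison p-values. Strain-level medians are related by ordinary
least-squares regression.

Dunn's test is implemented from its rank formulation (not delegated) so the
tie correction is explicit and testable against permutation oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DunnComparison",
    "kruskal_wallis",
    "dunn_sidak_adjust",
    "dunns_test",
    "median_regression_summary",
]


@dataclass
class DunnComparison:
    group: str
    control: str
    z: float
    p_raw: float
    p_adjusted: float


def _validate_groups(groups: dict) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} has zero observations")
        out[name] = arr
    return out


def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p on k-1 df.

    ``groups`` maps label -> per-cell values. Returns (H, p); H is 0 (p = 1)
    when all pooled values are identical.
    """
    gs = _validate_groups(groups)
    if sum(a.size for a in gs.values()) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(list(gs.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*gs.values())
    return float(h), float(p)


def dunn_sidak_adjust(p_raw: float, m: int) -> float:
    """Dunn-Sidak family adjustment: p_adj = 1 - (1 - p)^m."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p_raw) ** m)


def dunn_z_statistic(groups: dict, group_a: str, group_b: str) -> float:
    """Dunn's z on pooled ranks with tie correction for one pair."""
    gs = _validate_groups(groups)
    labels = list(gs)
    pooled = np.concatenate([gs[k] for k in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size

    mean_ranks = {}
    start = 0
    for k in labels:
        size = gs[k].size
        mean_ranks[k] = ranks[start : start + size].mean()
        start += size

    # tie correction: sum of (t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))

    var = (n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))) * (
        1.0 / gs[group_a].size + 1.0 / gs[group_b].size
    )
    if var <= 0:
        return 0.0
    return float((mean_ranks[group_a] - mean_ranks[group_b]) / np.sqrt(var))


def dunns_test(groups: dict, control: str) -> list[DunnComparison]:
    """Dunn's post-hoc test of every group against the control.

    Two-sided normal p-values, Dunn-Sidak adjusted over the m = k - 1
    comparisons in the family.
    """
    gs = _validate_groups(groups)
    if control not in gs:
        raise ValueError(f"control group {control!r} not present")
    others = [k for k in gs if k != control]
    if not others:
        raise ValueError("need at least one non-control group")
    m = len(others)

    results = []
    for name in others:
        z = dunn_z_statistic(groups, name, control)
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            DunnComparison(
                group=name,
                control=control,
                z=z,
                p_raw=p_raw,
                p_adjusted=dunn_sidak_adjust(p_raw, m),
            )
        )
    return results


def median_regression_summary(x_medians, y_medians) -> tuple[float, float, float]:
    """OLS of per-strain N_net medians on C_net medians.

    Returns (R^2, two-sided slope p-value, slope). Requires >= 3 strains and
    a non-degenerate predictor.
    """
    x = np.asarray(x_medians, dtype=float)
    y = np.asarray(y_medians, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 strains")
    if np.all(x == x[0]):
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)
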