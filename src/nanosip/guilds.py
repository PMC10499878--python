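"""Functional-guild assignment by K-means with elbow selection.

Builds a strain-level feature table (bacterial median daily C and N net
incorporation plus algal remineralization medians), z-standardizes it,
fits K-means across a range of candidate cluster counts, and selects the
cluster count at the elbow of the inertia curve (maximum curvature,
operationalized as the maximum second forward difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "GuildFeatureTable",
    "GuildResult",
    "FEATURE_COLUMNS",
    "build_feature_table",
    "kmeans_fit",
    "elbow_select",
    "assign_guilds",
]

#: The four strain-level medians used as clustering features.
FEATURE_COLUMNS = (
    "xnet_C_daily",
    "xnet_N_daily",
    "remin_C_daily",
    "remin_N_daily",
)


@dataclass
class GuildFeatureTable:
    strains: list[str]
    values: np.ndarray  # standardized, rows = strains
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped_strains: list[str] = field(default_factory=list)


@dataclass
class GuildResult:
    inertia_by_k: dict[int, float]
    chosen_k: int
    labels: dict[str, int]  # strain -> guild label in [1, chosen_k]
    seed: int
    n_init: int


def build_feature_table(
    strain_summaries: pd.DataFrame, drop_incomplete: bool = True
) -> GuildFeatureTable:
    """Standardized feature matrix from per-strain medians.

    Strains with any missing feature are dropped (and logged on the result)
    when ``drop_incomplete`` is set; at least 4 complete strains must
    remain. Columns are z-standardized (mean 0, SD 1).
    """
    missing_cols = [c for c in FEATURE_COLUMNS if c not in strain_summaries.columns]
    if missing_cols:
        raise ValueError(f"missing feature columns: {missing_cols}")
    feats = strain_summaries.loc[:, list(FEATURE_COLUMNS)].astype(float)
    incomplete = feats.index[feats.isna().any(axis=1)].tolist()
    if incomplete:
        if not drop_incomplete:
            raise ValueError(f"strains with missing features: {incomplete}")
        feats = feats.drop(index=incomplete)
    if len(feats) < 4:
        raise ValueError("need at least 4 complete strains for clustering")
    means = feats.mean(axis=0).to_numpy()
    sds = feats.std(axis=0, ddof=0).to_numpy()
    if np.any(sds == 0):
        raise ValueError("cannot standardize a zero-variance feature column")
    values = (feats.to_numpy() - means) / sds
    return GuildFeatureTable(
        strains=list(feats.index),
        values=values,
        column_means=means,
        column_sds=sds,
        dropped_strains=incomplete,
    )


def kmeans_fit(
    X: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` K-means fit; deterministic given the seed.

    Returns (labels, centroids, inertia) with labels in [1, k].
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of rows")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels + 1, km.cluster_centers_, float(km.inertia_)


def elbow_select(inertias: dict[int, float]) -> int:
    """Cluster count at the elbow of the inertia curve.

    The chosen k maximizes the second forward difference
    I(k-1) - 2 I(k) + I(k+1) over interior k of a consecutive k-range
    (maximum curvature); ties break toward the smaller k. A non-monotone
    inertia sequence draws a warning but still selects.
    """
    ks = sorted(inertias)
    if len(ks) < 4:
        raise ValueError("need at least 4 consecutive k values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k values must be consecutive")
    vals = np.array([inertias[k] for k in ks], dtype=float)
    if np.any(np.diff(vals) > 0):
        warnings.warn("inertia sequence is not non-increasing", stacklevel=2)
    curvature = vals[:-2] - 2.0 * vals[1:-1] + vals[2:]
    best = int(np.argmax(curvature))  # argmax returns the first (smallest k) on ties
    return ks[1 + best]


def assign_guilds(
    strain_summaries: pd.DataFrame,
    k_range: tuple[int, int] = (1, 6),
    seed: int = 0,
    n_init: int = 10,
    drop_incomplete: bool = True,
) -> GuildResult:
    """Full guild assignment: features -> inertia curve -> elbow -> labels."""
    table = build_feature_table(strain_summaries, drop_incomplete=drop_incomplete)
    k_lo, k_hi = k_range
    k_hi = min(k_hi, len(table.strains))
    inertias: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        labels, _, inertia = kmeans_fit(table.values, k, seed=seed, n_init=n_init)
        inertias[k] = inertia
        fits[k] = labels
    chosen = elbow_select(inertias)
    labels = {s: int(l) for s, l in zip(table.strains, fits[chosen])}
    return GuildResult(
        inertia_by_k=inertias,
        chosen_k=chosen,
        labels=labels,
        seed=seed,
        n_init=n_init,
    )
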