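"""Per-cell isotope statistics and net incorporation.

Converts measured secondary-ion ratios to minor-isotope atom fractions,
computes per-ROI cycle ratio statistics, net incorporation (``X_net``) with
substrate dilution bookkeeping, daily rates under the linear-accumulation
assumption, enrichment calls against killed controls, and the quartile
coefficient of dispersion.

Two ratio conventions are supported:

``CN_monomer``
    The measured ratio is the atomic ratio itself (e.g. 12C15N-/12C14N- =
    15N/14N), so ``f = r / (1 + r)``.
``C2_dimer``
    The measured dimer ratio is twice the atomic ratio (13C12C-/12C2- =
    2 * 13C/12C), so ``r = 2 f / (1 - f)`` and ``f = r / (2 + r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MAJOR_SPECIES, MINOR_SPECIES

__all__ = [
    "SubstrateSpec",
    "CycleRatioResult",
    "CellIsotopeRecord",
    "ratio_to_fraction",
    "fraction_to_ratio",
    "roi_cycle_ratios",
    "effective_substrate_fraction",
    "compute_xnet",
    "daily_rate",
    "enrichment_call",
    "coefficient_of_dispersion",
    "quantify_rois",
    "records_to_frame",
]

#: Ratio convention per element, matching the collected ion species.
ELEMENT_CONVENTION = {"C": "C2_dimer", "N": "CN_monomer"}


@dataclass(frozen=True)
class SubstrateSpec:
    """Isotope composition of the added substrates and incubation bookkeeping.

    Parameters
    ----------
    f_s_C_labeled, f_s_N_labeled : float
        Minor-isotope atom fraction of the added C / N substrate before any
        dilution by unlabeled background substrate.
    dilution_unlabeled : float
        Fraction of the total substrate pool that is unlabeled background
        material (0 for undiluted additions).
    duration_days : float
        Incubation length in days.
    """

    f_s_C_labeled: float
    f_s_N_labeled: float
    dilution_unlabeled: float = 0.0
    duration_days: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_s_C_labeled", "f_s_N_labeled", "dilution_unlabeled"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must be a fraction in [0, 1]")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")

    def labeled_fraction(self, element: str) -> float:
        if element == "C":
            return self.f_s_C_labeled
        if element == "N":
            return self.f_s_N_labeled
        raise ValueError(f"unknown element {element!r}")


@dataclass
class CycleRatioResult:
    """Per-cycle ROI ratios for one element with summary statistics."""

    ratios: np.ndarray  # ratios of the usable cycles, in cycle order
    mean: float
    sem: float
    n_cycles_used: int
    n_cycles_dropped: int


@dataclass
class CellIsotopeRecord:
    """Everything measured and derived for a single cell ROI."""

    roi_id: int
    kind: str = "unknown"
    attached: bool = False
    area_px: int = 0
    area_um2: float = float("nan")
    cycle_ratios_C: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_ratios_N: np.ndarray = field(default_factory=lambda: np.empty(0))
    ratio_mean_C: float = float("nan")
    ratio_sem_C: float = float("nan")
    ratio_mean_N: float = float("nan")
    ratio_sem_N: float = float("nan")
    f13C: float = float("nan")
    f15N: float = float("nan")
    xnet_C_total: float = float("nan")
    xnet_N_total: float = float("nan")
    xnet_C_daily: float = float("nan")
    xnet_N_daily: float = float("nan")
    enriched_C: bool = False
    enriched_N: bool = False


def ratio_to_fraction(r, convention: str):
    """Convert a measured ion ratio to a minor-isotope atom fraction.

    Parameters
    ----------
    r : float or array_like
        Non-negative measured ratio.
    convention : {"CN_monomer", "C2_dimer"}
        See module docstring.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("ratio must be non-negative")
    if convention == "CN_monomer":
        out = r / (1.0 + r)
    elif convention == "C2_dimer":
        out = r / (2.0 + r)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def fraction_to_ratio(f, convention: str):
    """Inverse of :func:`ratio_to_fraction` (bijective on f in [0, 1))."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("fraction must lie in [0, 1)")
    if convention == "CN_monomer":
        out = f / (1.0 - f)
    elif convention == "C2_dimer":
        out = 2.0 * f / (1.0 - f)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def _stack_counts(stacks, species: str) -> np.ndarray:
    obj = stacks[species]
    counts = getattr(obj, "counts", obj)
    return np.asarray(counts, dtype=float)


def roi_cycle_ratios(stacks, roi, element: str) -> CycleRatioResult:
    """Per-cycle minor/major ratio of a cell ROI, with mean and SEM.

    For each acquisition cycle the ratio is (ROI-summed minor counts) /
    (ROI-summed major counts). Cycles whose major-species ROI sum is zero are
    dropped and counted. The mean is the arithmetic mean over the usable
    cycles; the SEM is the sample standard deviation over cycles divided by
    sqrt(number of usable cycles).

    Parameters
    ----------
    stacks : mapping
        Species name -> cycles x rows x cols counts (arrays or objects with a
        ``counts`` attribute). Must contain the element's minor and major
        species.
    roi : CellROI or (rows, cols) index pair
        The pixel set of the cell.
    element : {"C", "N"}
    """
    minor = _stack_counts(stacks, MINOR_SPECIES[element])
    major = _stack_counts(stacks, MAJOR_SPECIES[element])
    if minor.shape != major.shape:
        raise ValueError("minor and major stacks must share shape")
    if minor.shape[0] < 1:
        raise ValueError("empty stack")

    pixels = getattr(roi, "pixels", roi)
    rows, cols = pixels
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("ROI has no pixels")
    if rows.max() >= minor.shape[1] or cols.max() >= minor.shape[2]:
        raise ValueError("ROI pixels fall outside the image")

    minor_sums = minor[:, rows, cols].sum(axis=1)
    major_sums = major[:, rows, cols].sum(axis=1)

    usable = major_sums > 0
    n_dropped = int(np.count_nonzero(~usable))
    if not np.any(usable):
        raise ValueError("no usable cycles: all cycles have zero major counts")

    ratios = minor_sums[usable] / major_sums[usable]
    mean = float(ratios.mean())
    if ratios.size >= 2:
        sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
    else:
        sem = float("nan")
    return CycleRatioResult(
        ratios=ratios,
        mean=mean,
        sem=sem,
        n_cycles_used=int(ratios.size),
        n_cycles_dropped=n_dropped,
    )


def effective_substrate_fraction(
    spec: SubstrateSpec, element: str, natural_fraction: float
) -> float:
    """Effective substrate isotope fraction after dilution by unlabeled pool.

    f_s = (1 - dilution) * f_labeled + dilution * natural_fraction
    """
    d = spec.dilution_unlabeled
    return (1.0 - d) * spec.labeled_fraction(element) + d * natural_fraction


def compute_xnet(f_f: float, f_i: float, f_s: float) -> float:
    """Net incorporation X_net in percent.

    X_net% = 100 * (f_f - f_i) / (f_s - f_i): the fraction of a cell's final
    elemental biomass newly synthesized from the labeled substrate. Values
    may be slightly negative under counting noise and are reported as-is.
    """
    if abs(f_s - f_i) < 1e-6:
        raise ValueError("substrate indistinguishable from background (f_s ~ f_i)")
    return 100.0 * (f_f - f_i) / (f_s - f_i)


def daily_rate(xnet_total: float, duration_days: float) -> float:
    """Total X_net% converted to %/day assuming linear biomass accumulation."""
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    return xnet_total / duration_days


def enrichment_call(f_cell: float, killed_values) -> bool:
    """True iff a cell is isotopically enriched relative to killed controls.

    The call is strict: ``f_cell > median(killed) + 3 * SD(killed)`` with the
    sample standard deviation (ddof=1). Requires at least 3 control cells.
    """
    killed = np.asarray(killed_values, dtype=float)
    if killed.size < 3:
        raise ValueError("need at least 3 killed-control cells")
    threshold = float(np.median(killed)) + 3.0 * float(killed.std(ddof=1))
    return bool(f_cell > threshold)


def coefficient_of_dispersion(values) -> float:
    """Quartile coefficient of dispersion, (Q3 - Q1) / (Q3 + Q1).

    Quartiles use linear interpolation between order statistics (the common
    "type 7" default). Requires n >= 4 and a positive scale Q1 + Q3.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    if q1 + q3 <= 0:
        raise ValueError("CD undefined for non-positive scale (Q1 + Q3 <= 0)")
    return float((q3 - q1) / (q3 + q1))


def quantify_rois(
    stacks,
    rois,
    substrate: SubstrateSpec,
    killed_fractions: dict[str, np.ndarray] | None = None,
    natural_fractions: dict[str, float] | None = None,
) -> list[CellIsotopeRecord]:
    """Full per-cell quantification for a set of ROIs.

    For each ROI and element, computes per-cycle ratios, converts the cycle-
    ratio mean to an atom fraction (f_f), and evaluates X_net with f_i taken
    as the median killed-control fraction (falling back to natural abundance
    when no killed controls are supplied) and f_s from the substrate spec.

    Parameters
    ----------
    stacks : mapping of species -> aligned, corrected stacks
    rois : iterable of CellROI
    substrate : SubstrateSpec
    killed_fractions : optional mapping {"C": array, "N": array}
        Per-cell killed-control fractions; drives both the baseline f_i
        (median) and the 3-SD enrichment call.
    natural_fractions : optional mapping {"C": f, "N": f}
        Natural-abundance fallback for f_i; defaults to the fixed constants.
    """
    from .constants import NATURAL_13C_FRACTION, NATURAL_15N_FRACTION

    if natural_fractions is None:
        natural_fractions = {"C": NATURAL_13C_FRACTION, "N": NATURAL_15N_FRACTION}

    records = []
    for roi in rois:
        rec = CellIsotopeRecord(
            roi_id=roi.roi_id,
            kind=getattr(roi, "kind", "unknown"),
            attached=getattr(roi, "attached", False),
            area_px=getattr(roi, "area_px", 0),
            area_um2=getattr(roi, "area_um2", float("nan")),
        )
        for element in ("C", "N"):
            res = roi_cycle_ratios(stacks, roi, element)
            f_f = ratio_to_fraction(res.mean, ELEMENT_CONVENTION[element])
            if killed_fractions is not None and element in killed_fractions:
                killed = np.asarray(killed_fractions[element], dtype=float)
                f_i = float(np.median(killed))
                enriched = enrichment_call(f_f, killed)
            else:
                f_i = natural_fractions[element]
                enriched = False
            f_s = effective_substrate_fraction(
                substrate, element, natural_fractions[element]
            )
            xnet = compute_xnet(f_f, f_i, f_s)
            xnet_day = daily_rate(xnet, substrate.duration_days)
            if element == "C":
                rec.cycle_ratios_C = res.ratios
                rec.ratio_mean_C, rec.ratio_sem_C = res.mean, res.sem
                rec.f13C = f_f
                rec.xnet_C_total, rec.xnet_C_daily = xnet, xnet_day
                rec.enriched_C = enriched
            else:
                rec.cycle_ratios_N = res.ratios
                rec.ratio_mean_N, rec.ratio_sem_N = res.mean, res.sem
                rec.f15N = f_f
                rec.xnet_N_total, rec.xnet_N_daily = xnet, xnet_day
                rec.enriched_N = enriched
        records.append(rec)
    return records


def records_to_frame(records):
    """Tabulate CellIsotopeRecords as a pandas DataFrame (one row per cell)."""
    import pandas as pd

    cols = [
        "roi_id", "kind", "attached", "area_px", "area_um2",
        "ratio_mean_C", "ratio_sem_C", "ratio_mean_N", "ratio_sem_N",
        "f13C", "f15N",
        "xnet_C_total", "xnet_N_total", "xnet_C_daily", "xnet_N_daily",
        "enriched_C", "enriched_N",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
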