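"""Raw ion-stack processing: dead-time correction, cycle registration,
accumulation, and ratio images.

An experiment is a mapping of species name -> :class:`IonImageStack`, all
sharing shape and acquisition metadata. Stacks are stored on disk in a
simple HDF5 layout (one integer dataset per species, attributes
``raster_um``, ``dwell_ms``, ``seed``); multi-page TIFF import is provided
for one-image-per-cycle dumps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import DEFAULT_DEAD_TIME_NS, ION_SPECIES

__all__ = [
    "IonImageStack",
    "RatioImage",
    "correct_dead_time",
    "register_cycles",
    "apply_shifts",
    "accumulate",
    "ratio_image",
    "write_experiment_h5",
    "read_experiment_h5",
    "import_tiff_stack",
]


@dataclass
class IonImageStack:
    """Multi-cycle ion-count images for one species.

    counts has shape (cycles, rows, cols); raw stacks are non-negative
    integers, dead-time-corrected stacks are real-valued.
    """

    species: str
    counts: np.ndarray
    dwell_ms: float = 1.0
    raster_um: float = 20.0
    cycle_shifts: list[tuple[int, int]] | None = None
    tau_ns: float | None = None  # set once dead-time corrected

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be cycles x rows x cols")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]


@dataclass
class RatioImage:
    """Per-pixel ratio of two accumulated ion images with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    numerator_species: str
    denominator_species: str
    min_denominator_counts: float


def correct_dead_time(stack: IonImageStack, tau_ns: float = DEFAULT_DEAD_TIME_NS) -> IonImageStack:
    """Correct electron-multiplier dead-time undercounting.

    With measured rate m = counts / dwell and dead time tau, the true rate is
    n = m / (1 - m * tau); counts are rescaled accordingly. Identity at
    tau = 0, monotone non-decreasing in m, and a pole at m * tau = 1.

    Raises
    ------
    ValueError
        If tau_ns < 0 or any pixel reaches saturation (m * tau >= 1); the
        error names the offending count.
    """
    if tau_ns < 0:
        raise ValueError("tau_ns must be non-negative")
    counts = stack.counts.astype(float)
    dwell_s = stack.dwell_ms * 1e-3
    tau_s = tau_ns * 1e-9
    m_tau = counts / dwell_s * tau_s
    if np.any(m_tau >= 1.0):
        worst = counts.flat[int(np.argmax(m_tau))]
        raise ValueError(
            f"dead-time saturation: pixel with {worst} counts in {stack.dwell_ms} ms "
            f"reaches m*tau >= 1 at tau = {tau_ns} ns"
        )
    corrected = counts / (1.0 - m_tau)
    out = replace(stack, counts=corrected)
    out.tau_ns = tau_ns
    return out


def _shift_image(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift by integer pixels, zero-filling exposed borders."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape images (nan if flat)."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


def register_cycles(
    stacks: dict[str, IonImageStack],
    reference_species: str = "12C14N",
    max_shift_px: int = 8,
) -> tuple[list[tuple[int, int]], dict[str, IonImageStack]]:
    """Estimate per-cycle integer drifts and realign all species.

    For each cycle of the reference species, the correction shift (dy, dx)
    within +/- max_shift_px maximizing normalized cross-correlation against
    cycle 0 is found by exhaustive search; the same correction is applied to
    every species. Ties (including flat images, where NCC is undefined) are
    broken toward the zero shift.

    Returns the list of applied corrections and the aligned stacks.
    """
    if reference_species not in stacks:
        raise ValueError(f"reference species {reference_species!r} not present")
    ref = stacks[reference_species]
    if ref.n_cycles < 2:
        raise ValueError("need at least 2 cycles to register")
    side = min(ref.shape)
    if max_shift_px >= side / 2:
        raise ValueError("max_shift_px must be < image side / 2")

    reference = ref.counts[0].astype(float)
    # candidates ordered by distance from zero so strict improvement keeps ties at 0
    candidates = sorted(
        (
            (dy, dx)
            for dy in range(-max_shift_px, max_shift_px + 1)
            for dx in range(-max_shift_px, max_shift_px + 1)
        ),
        key=lambda s: (max(abs(s[0]), abs(s[1])), abs(s[0]) + abs(s[1]), s),
    )

    shifts: list[tuple[int, int]] = [(0, 0)]
    for c in range(1, ref.n_cycles):
        img = ref.counts[c].astype(float)
        best, best_score = (0, 0), -np.inf
        for dy, dx in candidates:
            score = _ncc(reference, _shift_image(img, dy, dx))
            if np.isnan(score):
                continue
            if score > best_score:
                best, best_score = (dy, dx), score
        shifts.append(best)

    aligned = {name: apply_shifts(s, shifts) for name, s in stacks.items()}
    return shifts, aligned


def apply_shifts(stack: IonImageStack, shifts: list[tuple[int, int]]) -> IonImageStack:
    """Apply per-cycle integer corrections; shifted-out pixels are zero-filled."""
    if len(shifts) != stack.n_cycles:
        raise ValueError("one shift per cycle required")
    counts = np.stack(
        [_shift_image(stack.counts[c], dy, dx) for c, (dy, dx) in enumerate(shifts)]
    )
    out = replace(stack, counts=counts)
    out.cycle_shifts = list(shifts)
    return out


def accumulate(stack: IonImageStack) -> np.ndarray:
    """Sum an aligned stack over cycles into a single rows x cols image."""
    return stack.counts.sum(axis=0)


def ratio_image(
    numerator: np.ndarray,
    denominator: np.ndarray,
    min_denominator_counts: float = 1.0,
    numerator_species: str = "",
    denominator_species: str = "",
) -> RatioImage:
    """Pixel-wise ratio of accumulated images, masked where the denominator
    falls below ``min_denominator_counts``."""
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if numerator.shape != denominator.shape:
        raise ValueError("images must share shape")
    if min_denominator_counts <= 0:
        raise ValueError("min_denominator_counts must be positive")
    valid = denominator >= min_denominator_counts
    values = np.zeros_like(numerator)
    np.divide(numerator, denominator, out=values, where=valid)
    values[~valid] = np.nan
    return RatioImage(
        values=values,
        valid_mask=valid,
        numerator_species=numerator_species,
        denominator_species=denominator_species,
        min_denominator_counts=min_denominator_counts,
    )


# ---------------------------------------------------------------------------
# I/O


def write_experiment_h5(path, stacks: dict[str, IonImageStack], seed: int | None = None) -> None:
    """Write one dataset per species plus acquisition attributes."""
    import h5py

    first = next(iter(stacks.values()))
    with h5py.File(path, "w") as f:
        for name, stack in stacks.items():
            data = stack.counts
            if np.issubdtype(data.dtype, np.integer) or (
                np.issubdtype(data.dtype, np.floating) and np.all(data == np.round(data))
            ):
                ds = f.create_dataset(name, data=data.astype(np.int64))
            else:
                ds = f.create_dataset(name, data=data.astype(np.float64))
            if stack.tau_ns is not None:
                ds.attrs["tau_ns"] = stack.tau_ns
            if stack.cycle_shifts is not None:
                ds.attrs["cycle_shifts"] = np.asarray(stack.cycle_shifts)
        f.attrs["raster_um"] = first.raster_um
        f.attrs["dwell_ms"] = first.dwell_ms
        if seed is not None:
            f.attrs["seed"] = seed


def read_experiment_h5(path) -> dict[str, IonImageStack]:
    import h5py

    stacks: dict[str, IonImageStack] = {}
    with h5py.File(path, "r") as f:
        raster_um = float(f.attrs.get("raster_um", 20.0))
        dwell_ms = float(f.attrs.get("dwell_ms", 1.0))
        for name in f:
            ds = f[name]
            stack = IonImageStack(
                species=name,
                counts=ds[...],
                dwell_ms=dwell_ms,
                raster_um=raster_um,
            )
            if "tau_ns" in ds.attrs:
                stack.tau_ns = float(ds.attrs["tau_ns"])
            if "cycle_shifts" in ds.attrs:
                stack.cycle_shifts = [tuple(int(v) for v in s) for s in ds.attrs["cycle_shifts"]]
            stacks[name] = stack
    return stacks


def import_tiff_stack(
    path, species: str, dwell_ms: float = 1.0, raster_um: float = 20.0
) -> IonImageStack:
    """Import a multi-page TIFF (one page per cycle) as an IonImageStack."""
    import tifffile

    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None, ...]
    if species not in ION_SPECIES:
        raise ValueError(f"unknown species {species!r}")
    return IonImageStack(
        species=species, counts=counts, dwell_ms=dwell_ms, raster_um=raster_um
    )
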