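"""Ground-truthed synthetic nanoSIMS experiments.

Generates co-culture, axenic and killed-control ion-image stacks with known
per-cell isotope fractions so every downstream stage can be tested without
any instrument data. The forward model is deliberately simple:

* per-strain per-cell net incorporation (X_net) is drawn from a lognormal
  distribution parameterized by its median and quartile coefficient of
  dispersion, then inverted to a minor-isotope atom fraction;
* each pixel of each cycle is an independent Poisson draw whose mean is set
  by the species yield (inside-cell vs background) and, for the minor
  species, by the cell's isotope composition
  (13C12C/12C2 mean ratio = 2f/(1-f); 12C15N/12C14N mean ratio = f/(1-f));
* optional per-cycle integer drift exercises registration.

No QSA/matrix effects, detector aging, charging or beam PSF are modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import NATURAL_13C_FRACTION, NATURAL_15N_FRACTION
from .ion_imaging import IonImageStack, _shift_image
from .isotope_quant import SubstrateSpec, effective_substrate_fraction

__all__ = [
    "TruthCell",
    "IonYields",
    "GeneratorConfig",
    "lognormal_sigma_for_cd",
    "generate_strain_population",
    "place_cells_grid",
    "place_attached_bacterium",
    "render_ion_stacks",
    "generate_killed_control",
    "generate_axenic",
    "generate_guild_strain_table",
]

_Z75 = norm.ppf(0.75)  # 0.6744897501960817

_NATURAL = {"C": NATURAL_13C_FRACTION, "N": NATURAL_15N_FRACTION}


@dataclass
class TruthCell:
    """A planted cell with known ground-truth isotope composition."""

    cell_id: int
    kind: str  # algal | bacterial
    center: tuple[float, float]  # (row, col) pixels
    shape: str = "disk"  # disk | ellipse
    radii_um: tuple[float, float] = (0.5, 0.5)  # (row, col) semi-axes
    f13C_true: float = NATURAL_13C_FRACTION
    f15N_true: float = NATURAL_15N_FRACTION
    attached_to: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f13C_true <= 1.0 and 0.0 <= self.f15N_true <= 1.0):
            raise ValueError("isotope fractions must lie in [0, 1]")
        if min(self.radii_um) <= 0:
            raise ValueError("radii must be positive")
        if self.shape not in ("disk", "ellipse"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def mask(self, pixels: int, raster_um: float) -> np.ndarray:
        """Boolean pixel mask of this cell on the image grid."""
        px_per_um = pixels / raster_um
        ry = self.radii_um[0] * px_per_um
        rx = self.radii_um[1] * px_per_um
        yy, xx = np.ogrid[:pixels, :pixels]
        cy, cx = self.center
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


@dataclass
class IonYields:
    """Expected counts per pixel per cycle for the major species.

    Minor-species means follow from the isotope composition; background
    pixels sit at natural abundance. Defaults give a ~30 px bacterial ROI
    well over 1e4 accumulated CN counts in 24 cycles.
    """

    c2_cell: float = 80.0
    c2_background: float = 0.5
    cn_cell: float = 200.0
    cn_background: float = 0.5

    def __post_init__(self) -> None:
        for name in ("c2_cell", "c2_background", "cn_cell", "cn_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GeneratorConfig:
    """Acquisition geometry and noise model for the synthetic instrument."""

    raster_um: float = 20.0
    pixels: int = 256
    cycles: int = 24
    dwell_ms: float = 1.0
    ion_yields: IonYields = field(default_factory=IonYields)
    drift: list[tuple[int, int]] | None = None  # planted per-cycle (dy, dx)
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels < 16:
            raise ValueError("pixels must be >= 16")
        if self.cycles < 2:
            raise ValueError("cycles must be >= 2")
        if self.drift is not None and len(self.drift) != self.cycles:
            raise ValueError("drift must list one (dy, dx) per cycle")


def lognormal_sigma_for_cd(cd_target: float) -> float:
    """Log-scale sigma giving a lognormal the requested quartile CD.

    For X lognormal, Q3/Q1 = exp(2 z sigma) with z the 0.75 normal quantile,
    so CD = (Q3-Q1)/(Q3+Q1) = tanh(z sigma) and sigma = atanh(CD)/z.
    """
    if not 0.0 <= cd_target < 1.0:
        raise ValueError("cd_target must lie in [0, 1)")
    return math.atanh(cd_target) / _Z75


def generate_strain_population(
    median_xnet_daily: float,
    cd_target: float,
    days: float,
    substrate: SubstrateSpec,
    n: int,
    seed: int,
    element: str = "N",
) -> np.ndarray:
    """Draw per-cell final isotope fractions for one strain.

    Per-cell total X_net (as a fraction of final biomass) is lognormal with
    median ``median_xnet_daily * days`` and quartile coefficient of
    dispersion ``cd_target``; fractions are obtained by inverting
    f_f = f_i + X_net * (f_s - f_i) with f_i at natural abundance and f_s
    the diluted substrate fraction.

    Returns an array of n fractions in (0, 1).
    """
    total = median_xnet_daily * days
    if not 0.0 < total < 1.0:
        raise ValueError("median_xnet_daily * days must lie in (0, 1)")
    f_i = _NATURAL[element]
    f_s = effective_substrate_fraction(substrate, element, f_i)
    if f_s <= f_i:
        raise ValueError("substrate fraction must exceed natural abundance")

    sigma = lognormal_sigma_for_cd(cd_target)
    rng = np.random.default_rng(seed)
    if sigma == 0.0:
        xnet = np.full(n, total)
    else:
        xnet = total * np.exp(sigma * rng.standard_normal(n))
    f_f = f_i + xnet * (f_s - f_i)
    if np.any((f_f <= 0.0) | (f_f >= 1.0)):
        raise ValueError(
            "configuration error: inverted fractions fall outside (0, 1); "
            "reduce median_xnet_daily, days or cd_target"
        )
    return f_f


# ---------------------------------------------------------------------------
# Cell placement


def place_cells_grid(
    n: int,
    radius_um: float,
    config: GeneratorConfig,
    kind: str = "bacterial",
    f13C=None,
    f15N=None,
    clearance_px: int = 3,
    start_id: int = 1,
) -> list[TruthCell]:
    """Place n disk cells of one strain on a regular non-overlapping grid.

    Free-living cells keep >= ``clearance_px`` pixels between boundaries.
    Raises if the field cannot hold n cells at this size.
    """
    px_per_um = config.pixels / config.raster_um
    r_px = radius_um * px_per_um
    pitch = int(math.ceil(2 * r_px + clearance_px))
    margin = int(math.ceil(r_px)) + 1
    positions = [
        (float(y), float(x))
        for y in range(margin, config.pixels - margin, pitch)
        for x in range(margin, config.pixels - margin, pitch)
    ]
    if len(positions) < n:
        raise ValueError(
            f"field of {config.pixels} px holds only {len(positions)} cells "
            f"of radius {radius_um} um; requested {n}"
        )
    f13C = np.broadcast_to(
        NATURAL_13C_FRACTION if f13C is None else np.asarray(f13C, dtype=float), (n,)
    )
    f15N = np.broadcast_to(
        NATURAL_15N_FRACTION if f15N is None else np.asarray(f15N, dtype=float), (n,)
    )
    return [
        TruthCell(
            cell_id=start_id + i,
            kind=kind,
            center=positions[i],
            radii_um=(radius_um, radius_um),
            f13C_true=float(f13C[i]),
            f15N_true=float(f15N[i]),
        )
        for i in range(n)
    ]


def place_attached_bacterium(
    host: TruthCell,
    radius_um: float,
    config: GeneratorConfig,
    cell_id: int,
    angle_rad: float = 0.0,
    gap_px: float = 1.0,
    f13C: float = NATURAL_13C_FRACTION,
    f15N: float = NATURAL_15N_FRACTION,
) -> TruthCell:
    """Place a bacterium with its boundary within ~2 px of the host boundary."""
    px_per_um = config.pixels / config.raster_um
    d = (max(host.radii_um) + radius_um) * px_per_um + gap_px
    cy = host.center[0] + d * math.sin(angle_rad)
    cx = host.center[1] + d * math.cos(angle_rad)
    return TruthCell(
        cell_id=cell_id,
        kind="bacterial",
        center=(cy, cx),
        radii_um=(radius_um, radius_um),
        f13C_true=f13C,
        f15N_true=f15N,
        attached_to=host.cell_id,
    )


# ---------------------------------------------------------------------------
# Rendering


def _mean_images(cells: list[TruthCell], config: GeneratorConfig):
    """Per-species expected-count images plus the painted truth areas."""
    y = config.ion_yields
    n = config.pixels
    f13_bg, f15_bg = NATURAL_13C_FRACTION, NATURAL_15N_FRACTION
    means = {
        "12C2": np.full((n, n), y.c2_background, dtype=float),
        "13C12C": np.full((n, n), y.c2_background * 2 * f13_bg / (1 - f13_bg)),
        "12C14N": np.full((n, n), y.cn_background, dtype=float),
        "12C15N": np.full((n, n), y.cn_background * f15_bg / (1 - f15_bg)),
    }
    algal_cover = np.zeros((n, n), dtype=np.int32)
    areas: dict[int, int] = {}
    for cell in cells:
        mask = cell.mask(n, config.raster_um)
        if not mask.any():
            raise ValueError(f"cell {cell.cell_id} covers no pixels")
        if np.any(mask & (algal_cover > 0)) and not config.allow_overlap:
            if cell.kind == "algal":
                raise ValueError(
                    f"algal cell {cell.cell_id} overlaps another algal cell"
                )
        if cell.kind == "algal":
            algal_cover[mask] += 1
        areas[cell.cell_id] = int(mask.sum())
        f13, f15 = cell.f13C_true, cell.f15N_true
        means["12C2"][mask] = y.c2_cell
        means["13C12C"][mask] = y.c2_cell * 2 * f13 / (1 - f13)
        means["12C14N"][mask] = y.cn_cell
        means["12C15N"][mask] = y.cn_cell * f15 / (1 - f15)
    return means, areas


def render_ion_stacks(
    cells: list[TruthCell],
    config: GeneratorConfig,
    noiseless: bool = False,
) -> tuple[dict[str, IonImageStack], pd.DataFrame]:
    """Render the four-species ion stacks for a set of planted cells.

    Counts are independent Poisson draws around the per-pixel means (or the
    exact means when ``noiseless`` is set, for round-trip checks). Identical
    (cells, config) including seed gives bit-identical output.

    Returns (stacks, truth table).
    """
    n = config.pixels
    for cell in cells:
        cy, cx = cell.center
        if not (0 <= cy < n and 0 <= cx < n):
            raise ValueError(f"cell {cell.cell_id} center outside the raster")
    means, areas = _mean_images(cells, config)

    rng = np.random.default_rng(config.seed)
    stacks: dict[str, IonImageStack] = {}
    for species in ("12C2", "13C12C", "12C14N", "12C15N"):
        mean = means[species]
        if config.drift is not None:
            per_cycle = np.stack(
                [_shift_image(mean, dy, dx) for (dy, dx) in config.drift]
            )
        else:
            per_cycle = np.broadcast_to(mean, (config.cycles, n, n))
        if noiseless:
            counts = np.array(per_cycle, dtype=float)
        else:
            counts = rng.poisson(per_cycle, size=(config.cycles, n, n))
        stacks[species] = IonImageStack(
            species=species,
            counts=counts,
            dwell_ms=config.dwell_ms,
            raster_um=config.raster_um,
        )

    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "kind": [c.kind for c in cells],
            "center_row": [c.center[0] for c in cells],
            "center_col": [c.center[1] for c in cells],
            "f13C_true": [c.f13C_true for c in cells],
            "f15N_true": [c.f15N_true for c in cells],
            "area_px": [areas[c.cell_id] for c in cells],
            "attached_to": [c.attached_to for c in cells],
        }
    )
    return stacks, truth


def generate_killed_control(
    config: GeneratorConfig,
    n_cells: int = 50,
    radius_um: float = 0.35,
    kind: str = "bacterial",
) -> tuple[dict[str, IonImageStack], pd.DataFrame]:
    """Formalin-killed control: every cell at natural-abundance fractions."""
    cells = place_cells_grid(n_cells, radius_um, config, kind=kind)
    return render_ion_stacks(cells, config)


def generate_axenic(
    config: GeneratorConfig,
    n_cells: int = 50,
    radius_um: float = 1.5,
    enriched_subpopulation_fraction: float = 0.0,
    f13C_enriched: float = 0.02,
) -> tuple[dict[str, IonImageStack], pd.DataFrame]:
    """Axenic algal culture; optionally a subpopulation carries elevated 13C.

    With ``enriched_subpopulation_fraction`` = 0.18, 18% of the algal cells
    (rounded to the nearest whole cell) are planted isotopically enriched in
    13C while the rest sit at natural abundance.
    """
    if not 0.0 <= enriched_subpopulation_fraction <= 1.0:
        raise ValueError("enriched_subpopulation_fraction must be a fraction")
    n_enriched = int(round(n_cells * enriched_subpopulation_fraction))
    f13 = np.full(n_cells, NATURAL_13C_FRACTION)
    if n_enriched:
        rng = np.random.default_rng(config.seed)
        enriched_idx = rng.choice(n_cells, size=n_enriched, replace=False)
        f13[enriched_idx] = f13C_enriched
    cells = place_cells_grid(
        n_cells, radius_um, config, kind="algal", f13C=f13
    )
    return render_ion_stacks(cells, config)


def generate_guild_strain_table(
    archetypes,
    strains_per_archetype,
    within_sd: float,
    seed: int,
    missing_strains: int = 0,
) -> pd.DataFrame:
    """Strain-level medians drawn around guild archetype centroids.

    ``archetypes`` is a list of (C_net, N_net, remin_C, remin_N) centroids;
    each strain's four features are its archetype centroid plus N(0,
    within_sd) noise. ``missing_strains`` strains get NaN remineralization
    features to exercise the incomplete-row drop rule.

    Returns a DataFrame indexed by strain with columns xnet_C_daily,
    xnet_N_daily, remin_C_daily, remin_N_daily and the true archetype label.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for a_idx, centroid in enumerate(archetypes):
        centroid = np.asarray(centroid, dtype=float)
        for _ in range(strains_per_archetype):
            feats = centroid + within_sd * rng.standard_normal(4)
            rows.append(
                {
                    "strain": f"strain_{sid:02d}",
                    "xnet_C_daily": feats[0],
                    "xnet_N_daily": feats[1],
                    "remin_C_daily": feats[2],
                    "remin_N_daily": feats[3],
                    "archetype": a_idx,
                }
            )
            sid += 1
    df = pd.DataFrame(rows).set_index("strain")
    if missing_strains:
        drop_idx = rng.choice(len(df), size=missing_strains, replace=False)
        for i in drop_idx:
            df.iloc[i, df.columns.get_loc("remin_C_daily")] = np.nan
            df.iloc[i, df.columns.get_loc("remin_N_daily")] = np.nan
    return df
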