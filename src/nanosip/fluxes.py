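"""Population-level volumetric fluxes from per-cell incorporation.

Combines cell geometry (projected ROI area -> biovolume), allometric
element content, strain abundances and median daily net incorporation into
volumetric fluxes in ug element per liter per day.

The allometric size-to-carbon relation (C = a * V^b) and the C:N mass ratio
are configuration values with common bacterioplankton defaults; fluxes are
lower-bound estimates under the linear biomass-accumulation assumption and
no correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrainAbundance",
    "FluxRecord",
    "area_to_biovolume",
    "biovolume_to_content",
    "population_flux",
    "microscopy_cell_density",
    "strain_flux_table",
]

#: Allometric defaults: C[fg] = a * (V[um^3])^b, N = C / cn_ratio.
DEFAULT_ALLOMETRY = {"a": 120.0, "b": 0.72, "cn_ratio": 4.0}


@dataclass(frozen=True)
class StrainAbundance:
    strain: str
    cells_per_ml: float
    source: str = "flow_cytometry"  # flow_cytometry | microscopy

    def __post_init__(self) -> None:
        if self.cells_per_ml < 0:
            raise ValueError("cell density must be non-negative")


@dataclass
class FluxRecord:
    strain: str
    median_xnet_daily_C: float
    median_xnet_daily_N: float
    cell_content_fg_C: float
    cell_content_fg_N: float
    flux_ug_per_l_per_day_C: float
    flux_ug_per_l_per_day_N: float


def area_to_biovolume(area_um2: float, shape: str = "sphere", aspect_ratio: float = 1.0) -> float:
    """Biovolume (um^3) of a cell from its projected area.

    sphere: diameter d = 2 sqrt(A/pi), V = pi d^3 / 6.
    rod: cylinder with hemispherical caps at the given length:width aspect
    ratio, with width chosen so the projected capsule area matches A; at
    aspect_ratio = 1 this reduces to the sphere.
    """
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if shape == "sphere":
        d = 2.0 * math.sqrt(area_um2 / math.pi)
        return math.pi * d**3 / 6.0
    if shape == "rod":
        if aspect_ratio < 1.0:
            raise ValueError("aspect_ratio must be >= 1 for a rod")
        # projected area of a capsule: W^2 (AR - 1) + pi W^2 / 4
        w = math.sqrt(area_um2 / (aspect_ratio - 1.0 + math.pi / 4.0))
        return math.pi * w**3 * ((aspect_ratio - 1.0) / 4.0 + 1.0 / 6.0)
    raise ValueError(f"unknown shape {shape!r}")


def biovolume_to_content(
    volume_um3: float,
    a: float = DEFAULT_ALLOMETRY["a"],
    b: float = DEFAULT_ALLOMETRY["b"],
    cn_ratio: float = DEFAULT_ALLOMETRY["cn_ratio"],
) -> tuple[float, float]:
    """Per-cell C and N content in fg from biovolume: C = a V^b, N = C/cn."""
    if volume_um3 < 0:
        raise ValueError("volume must be non-negative")
    if a <= 0:
        raise ValueError("allometric prefactor must be positive")
    if cn_ratio <= 0:
        raise ValueError("cn_ratio must be positive")
    c_fg = a * volume_um3**b if volume_um3 > 0 else 0.0
    return c_fg, c_fg / cn_ratio


def population_flux(cells_per_ml: float, content_fg: float, xnet_daily: float) -> float:
    """Volumetric incorporation flux in ug element L^-1 d^-1.

    flux = cells_per_ml * 1e3 [cells/L] * content_fg * 1e-9 [ug/cell]
    * xnet_daily / 100. Negative rates are floored to zero (a negative flux
    is meaningless).
    """
    if cells_per_ml < 0 or content_fg < 0:
        raise ValueError("abundance and content must be non-negative")
    rate = max(xnet_daily, 0.0)
    return cells_per_ml * 1e3 * content_fg * 1e-9 * rate / 100.0


def microscopy_cell_density(
    mean_per_fov: float,
    filter_area: float,
    fov_area: float,
    volume_ml: float,
    dilution_factor: float = 1.0,
) -> float:
    """Cells/mL from microscopy counts.

    density = mean cells per field of view * (total filter area / field of
    view area) / volume filtered * dilution factor. Areas may be in any one
    consistent unit.
    """
    if fov_area <= 0:
        raise ValueError("fov_area must be positive")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return mean_per_fov * (filter_area / fov_area) / volume_ml * dilution_factor


def strain_flux_table(
    strain_summaries: pd.DataFrame,
    abundances: dict[str, float],
    shape: str = "sphere",
    aspect_ratio: float = 1.0,
    allometry: dict | None = None,
) -> pd.DataFrame:
    """Per-strain flux table from strain summaries and abundances.

    ``strain_summaries`` must be indexed by strain with columns
    ``median_xnet_C_daily``, ``median_xnet_N_daily`` and
    ``median_area_um2`` (median bacterial ROI area of that strain).
    """
    allo = dict(DEFAULT_ALLOMETRY)
    if allometry:
        allo.update(allometry)
    rows = []
    for strain, row in strain_summaries.iterrows():
        volume = area_to_biovolume(row["median_area_um2"], shape, aspect_ratio)
        c_fg, n_fg = biovolume_to_content(volume, **allo)
        density = abundances.get(strain, np.nan)
        rows.append(
            {
                "strain": strain,
                "cells_per_ml": density,
                "biovolume_um3": volume,
                "cell_content_fg_C": c_fg,
                "cell_content_fg_N": n_fg,
                "median_xnet_C_daily": row["median_xnet_C_daily"],
                "median_xnet_N_daily": row["median_xnet_N_daily"],
                "flux_ug_C_per_l_per_day": population_flux(
                    density, c_fg, row["median_xnet_C_daily"]
                )
                if np.isfinite(density)
                else np.nan,
                "flux_ug_N_per_l_per_day": population_flux(
                    density, n_fg, row["median_xnet_N_daily"]
                )
                if np.isfinite(density)
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("strain")
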