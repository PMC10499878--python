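"""ROI segmentation of secondary-ion images.

Mirrors a dual strategy: cells are found on the accumulated 12C14N- image
(Otsu threshold + 8-connected components), while isotopically enriched
bacteria may instead be segmented on the 15N/14N ratio image against
killed-control statistics. ROIs are classified algal vs bacterial by an
area gate and bacteria are flagged as algal-attached by pixel proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .ion_imaging import RatioImage

__all__ = [
    "CellROI",
    "segment_cn",
    "segment_bacteria_by_ratio",
    "classify_and_flag",
    "rois_from_labels",
    "subtract_bacterial_pixels",
    "write_label_tiff",
    "read_label_tiff",
    "roi_table",
]


@dataclass
class CellROI:
    """A labeled pixel set treated as one cell."""

    roi_id: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) index arrays
    kind: str = "unknown"  # algal | bacterial | unknown
    attached: bool = False
    area_px: int = 0
    area_um2: float = float("nan")

    def __post_init__(self) -> None:
        if self.area_px == 0:
            self.area_px = int(self.pixels[0].size)

    def centroid(self) -> tuple[float, float]:
        return float(self.pixels[0].mean()), float(self.pixels[1].mean())


def segment_cn(cn_image: np.ndarray, min_area_px: int = 5) -> np.ndarray:
    """Label cells on an accumulated 12C14N image.

    Foreground by Otsu threshold, 8-connected components, components smaller
    than ``min_area_px`` discarded. Returns a label map (background 0). An
    all-constant image yields zero ROIs with a warning.
    """
    cn_image = np.asarray(cn_image, dtype=float)
    if cn_image.size == 0:
        raise ValueError("empty image")
    if np.all(cn_image == cn_image.flat[0]):
        warnings.warn("constant image: no cells segmented", stacklevel=2)
        return np.zeros(cn_image.shape, dtype=np.int32)
    thresh = threshold_otsu(cn_image)
    mask = cn_image > thresh
    return _labeled_components(mask, min_area_px)


def segment_bacteria_by_ratio(
    ratio: RatioImage,
    killed_stats: tuple[float, float],
    min_area_px: int = 5,
) -> np.ndarray:
    """Label enriched bacteria on a 15N/14N ratio image.

    Foreground = valid pixels whose ratio exceeds killed median + 3 * killed
    SD; 8-connected components, size-filtered.
    """
    killed_median, killed_sd = killed_stats
    if killed_sd < 0:
        raise ValueError("killed-control SD must be non-negative")
    threshold = killed_median + 3.0 * killed_sd
    with np.errstate(invalid="ignore"):
        mask = ratio.valid_mask & (ratio.values > threshold)
    return _labeled_components(mask, min_area_px)


def _labeled_components(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    labels = cc_label(mask, connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(areas >= min_area_px)
        keep = keep[keep > 0]
        relabel = np.zeros(labels.max() + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    return labels.astype(np.int32)


def classify_and_flag(
    labels: np.ndarray,
    algal_min_area_px: int = 80,
    adjacency_px: int = 2,
    raster_um: float = 20.0,
) -> list[CellROI]:
    """Turn a label map into classified CellROIs with attachment flags.

    ROIs with area >= ``algal_min_area_px`` are algal (inclusive gate), the
    rest bacterial. A bacterial ROI is flagged attached when any of its
    pixels lies within ``adjacency_px`` Chebyshev distance of an algal pixel.
    Algal ROIs are never flagged.
    """
    if adjacency_px < 0:
        raise ValueError("adjacency_px must be non-negative")
    labels = np.asarray(labels)
    px_um = raster_um / labels.shape[1]

    rois: list[CellROI] = []
    algal_mask = np.zeros(labels.shape, dtype=bool)
    for roi_id in np.unique(labels):
        if roi_id == 0:
            continue
        pixels = np.nonzero(labels == roi_id)
        area = pixels[0].size
        kind = "algal" if area >= algal_min_area_px else "bacterial"
        if kind == "algal":
            algal_mask[pixels] = True
        rois.append(
            CellROI(
                roi_id=int(roi_id),
                pixels=pixels,
                kind=kind,
                area_px=int(area),
                area_um2=float(area * px_um**2),
            )
        )

    if algal_mask.any() and adjacency_px >= 0:
        # Chebyshev distance transform: dilate algal mask with a square footprint
        structure = np.ones((2 * adjacency_px + 1, 2 * adjacency_px + 1), dtype=bool)
        near_algal = (
            ndimage.binary_dilation(algal_mask, structure=structure)
            if adjacency_px > 0
            else algal_mask
        )
        for roi in rois:
            if roi.kind == "bacterial" and near_algal[roi.pixels].any():
                roi.attached = True
    return rois


def rois_from_labels(
    labels: np.ndarray, kind: str = "unknown", raster_um: float = 20.0
) -> list[CellROI]:
    """Wrap an externally supplied label map (e.g. manual masks) as CellROIs."""
    labels = np.asarray(labels)
    px_um = raster_um / labels.shape[1]
    out = []
    for roi_id in np.unique(labels):
        if roi_id == 0:
            continue
        pixels = np.nonzero(labels == roi_id)
        out.append(
            CellROI(
                roi_id=int(roi_id),
                pixels=pixels,
                kind=kind,
                area_px=int(pixels[0].size),
                area_um2=float(pixels[0].size * px_um**2),
            )
        )
    return out


def subtract_bacterial_pixels(
    algal_labels: np.ndarray, bacterial_labels: np.ndarray, dilate_px: int = 1
) -> np.ndarray:
    """Remove (dilated) bacterial pixels from algal ROIs.

    Keeps algal ROIs free of attached-bacteria signal: bacterial ROI pixels
    are dilated by ``dilate_px`` and zeroed out of the algal label map.
    """
    bact_mask = np.asarray(bacterial_labels) > 0
    if dilate_px > 0:
        structure = np.ones((2 * dilate_px + 1, 2 * dilate_px + 1), dtype=bool)
        bact_mask = ndimage.binary_dilation(bact_mask, structure=structure)
    out = np.asarray(algal_labels).copy()
    out[bact_mask] = 0
    return out


def write_label_tiff(path, labels: np.ndarray) -> None:
    import tifffile

    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(np.int32)


def roi_table(rois: list[CellROI]):
    """ROI summary as a DataFrame (roi_id, kind, attached, areas, centroid)."""
    import pandas as pd

    rows = []
    for r in rois:
        cy, cx = r.centroid()
        rows.append(
            {
                "roi_id": r.roi_id,
                "kind": r.kind,
                "attached": r.attached,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "centroid_row": cy,
                "centroid_col": cx,
            }
        )
    return pd.DataFrame(rows)
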