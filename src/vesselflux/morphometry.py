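"""Invasion and shape quantification from segmentation masks and images.

Implements the image-analysis chain used on confocal projections of the
co-culture device: F-actin-based cell segmentation (Gaussian blur -> Otsu ->
connected components), per-cell shape descriptors (area, perimeter,
circularity 4*pi*A/P^2, equivalent-ellipse aspect ratio), nucleus-based
invasion distances from the tumor-channel edge, focal-adhesion puncta
counting, the peri-cellular collagen contraction ratio, 2D motility metrics,
and aspect-ratio pseudo-color maps.

Coordinate convention: pixel centers, 0-based indices, x (= image column)
increases toward the endothelial channel. Every CSV written by this module
states the convention in a header line.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

from .exceptions import ParameterError

__all__ = [
    "LabelMask",
    "InvasionResult",
    "segment_cells",
    "shape_descriptors",
    "invasion_distances",
    "count_adhesions",
    "collagen_contraction_ratio",
    "motility_metrics",
    "aspect_ratio_map",
]

logger = logging.getLogger(__name__)

COORDINATE_NOTE = (
    "pixel centers, 0-based indices, x increases toward the EC channel"
)


@dataclass(frozen=True)
class LabelMask:
    """Integer label image (0 = background) with its pixel pitch in µm."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 2:
            raise ParameterError("label image must be 2D")
        if labels.min() < 0:
            raise ParameterError("labels must be non-negative")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


def segment_cells(
    intensity_image: np.ndarray,
    pixel_size: float,
    blur_sigma: float = 2.0,
    min_area_um2: float = 25.0,
) -> LabelMask:
    """Gaussian blur -> Otsu threshold -> connected components -> size filter.

    Deterministic. An image that thresholds to all-background returns an
    empty mask with a logged warning rather than raising.
    """
    img = np.asarray(intensity_image, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ParameterError("expected a 2D non-negative intensity image")
    blurred = filters.gaussian(img, sigma=blur_sigma, preserve_range=True)
    if np.ptp(blurred) == 0:
        logger.warning("image has no contrast; returning empty mask")
        return LabelMask(np.zeros_like(img, dtype=np.int32), pixel_size)
    thr = filters.threshold_otsu(blurred)
    binary = blurred > thr
    if not binary.any():
        logger.warning("all pixels below Otsu threshold; returning empty mask")
        return LabelMask(np.zeros_like(img, dtype=np.int32), pixel_size)
    min_px = max(int(round(min_area_um2 / pixel_size**2)), 1)
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)
    labels = measure.label(binary, connectivity=1)
    return LabelMask(labels.astype(np.int32), pixel_size)


def shape_descriptors(mask: LabelMask, min_area_px: int = 5) -> pd.DataFrame:
    """Per-cell centroid, area, perimeter, circularity and aspect ratio.

    Circularity 4*pi*A/P^2 is capped at 1.0 (digital perimeters can push it
    slightly above); the raw value is retained in ``circularity_raw``.
    Aspect ratio is the major/minor axis ratio of the second-central-moment
    equivalent ellipse. Border-touching cells are flagged, not dropped;
    objects below ``min_area_px`` pixels are excluded.
    """
    labels = mask.labels
    if labels.max() == 0:
        raise ParameterError("mask contains no labels")
    h, w = labels.shape
    px = mask.pixel_size
    rows = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        perimeter = rp.perimeter * px
        area = rp.area * px**2
        circ_raw = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else np.nan
        minor = rp.axis_minor_length
        ar = rp.axis_major_length / minor if minor > 0 else np.inf
        rmin, cmin, rmax, cmax = rp.bbox
        rows.append(
            {
                "cell_id": int(rp.label),
                "centroid_x_um": rp.centroid[1] * px,
                "centroid_y_um": rp.centroid[0] * px,
                "area_um2": area,
                "perimeter_um": perimeter,
                "circularity": min(circ_raw, 1.0),
                "circularity_raw": circ_raw,
                "aspect_ratio": ar,
                "touches_border": rmin == 0 or cmin == 0 or rmax == h or cmax == w,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InvasionResult:
    distances: np.ndarray           # µm, signed (+ = toward the EC channel)
    mean: float
    sem: float
    mean_positive_only: float
    normalized: Optional[np.ndarray] = None  # distances / control mean


def invasion_distances(
    nuclei_x: np.ndarray,
    channel_edge_x: float,
    control_mean: Optional[float] = None,
) -> InvasionResult:
    """Signed nucleus displacements from the tumor-channel edge.

    ``distance_i = x_i - channel_edge_x`` in the shared coordinate frame
    (positive toward the EC channel). When ``control_mean`` is given,
    per-cell distances normalized to that control mean are included.
    """
    x = np.asarray(nuclei_x, dtype=float)
    if x.size == 0:
        raise ParameterError("no nucleus positions given")
    d = x - channel_edge_x
    positive = d[d > 0]
    normalized = d / control_mean if control_mean else None
    return InvasionResult(
        distances=d,
        mean=float(d.mean()),
        sem=float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0,
        mean_positive_only=float(positive.mean()) if positive.size else 0.0,
        normalized=normalized,
    )


def count_adhesions(
    pfak_image: np.ndarray,
    mask: LabelMask,
    min_size_um2: float = 0.2,
    tophat_radius_px: int = 4,
) -> pd.DataFrame:
    """Count pFAK-positive puncta and their mean size per cell.

    Within each cell: top-hat background suppression, Otsu threshold on the
    within-cell intensities, connected puncta of at least ``min_size_um2``.
    A cell with no intensity variation counts zero adhesions.
    """
    img = np.asarray(pfak_image, dtype=float)
    if img.shape != mask.labels.shape:
        raise ParameterError("pfak image and mask shapes differ")
    px = mask.pixel_size
    min_px = max(int(round(min_size_um2 / px**2)), 1)
    tophat = morphology.white_tophat(img, footprint=morphology.disk(tophat_radius_px))
    rows = []
    for rp in measure.regionprops(mask.labels):
        cell = mask.labels == rp.label
        # the top-hat leaves a rim artifact along the cell boundary; restrict
        # counting to a border-eroded core
        core = morphology.erosion(cell, morphology.disk(tophat_radius_px))
        if core.any():
            cell = core
        values = tophat[cell]
        if np.ptp(values) == 0:
            rows.append({"cell_id": int(rp.label), "adhesion_count": 0,
                         "adhesion_mean_size_um2": np.nan})
            continue
        thr = filters.threshold_otsu(values)
        puncta = np.zeros_like(cell)
        puncta[cell] = tophat[cell] > thr
        plabels = measure.label(puncta, connectivity=1)
        sizes = np.bincount(plabels.ravel())[1:]
        kept = sizes[sizes >= min_px]
        rows.append(
            {
                "cell_id": int(rp.label),
                "adhesion_count": int(len(kept)),
                "adhesion_mean_size_um2": float(kept.mean() * px**2) if len(kept) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def collagen_contraction_ratio(
    reflectance_image: np.ndarray,
    mask: LabelMask,
    ring_width_um: float = 10.0,
    tubeness_scale_px: float = 2.0,
) -> Dict[str, float]:
    """Peri-cellular vs bulk collagen intensity ratio.

    A Hessian ridge (tubeness/Sato) filter at the given scale isolates
    fiber-like structures; reflectance intensity is then compared between a
    ``ring_width_um`` dilation ring around the cells (peripheral) and the
    remaining matrix (bulk), restricted to fiber pixels when fibers occupy a
    meaningful fraction of each region. Invariant to global multiplicative
    intensity scaling.
    """
    img = np.asarray(reflectance_image, dtype=float)
    if img.shape != mask.labels.shape:
        raise ParameterError("reflectance image and mask shapes differ")
    if ring_width_um <= 0:
        raise ParameterError("ring_width_um must be > 0")
    ring_px = max(int(round(ring_width_um / mask.pixel_size)), 1)
    cells = mask.labels > 0
    dilated = morphology.dilation(cells, morphology.disk(ring_px))
    peripheral = dilated & ~cells
    bulk = ~dilated
    if not bulk.any():
        raise ParameterError(
            "no bulk (non-peripheral) matrix remains; cells too dense for this "
            "field of view - use a larger field"
        )
    if not peripheral.any():
        raise ParameterError("no peripheral ring pixels (empty mask?)")

    tub = filters.sato(img, sigmas=[tubeness_scale_px], black_ridges=False)
    if np.ptp(tub) > 0:
        fiber = tub > filters.threshold_otsu(tub)
    else:
        fiber = np.ones_like(cells)
    regions = {}
    for name, region in (("peripheral", peripheral), ("bulk", bulk)):
        sel = region & fiber
        if sel.sum() < 0.01 * region.sum():
            sel = region  # fibers too sparse in this region; use all pixels
        regions[name] = float(img[sel].mean())
    return {
        "ratio": regions["peripheral"] / regions["bulk"],
        "peripheral_mean": regions["peripheral"],
        "bulk_mean": regions["bulk"],
        "ring_width_um": float(ring_width_um),
    }


def motility_metrics(tracks: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean speed per track and origin-centered paths (for rose plots).

    ``tracks`` columns: track_id, t_s, x_um, y_um; each track needs >= 2
    points with strictly increasing, non-duplicated timestamps. Mean speed is
    total path length over total duration, reported in µm/min.
    """
    required = {"track_id", "t_s", "x_um", "y_um"}
    if not required.issubset(tracks.columns):
        raise ParameterError(f"track table must have columns {sorted(required)}")
    speeds = []
    paths = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ParameterError(f"track {tid!r} has fewer than 2 points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ParameterError(f"track {tid!r} has duplicate or unordered timestamps")
        x = grp["x_um"].to_numpy(dtype=float)
        y = grp["y_um"].to_numpy(dtype=float)
        steps = np.hypot(np.diff(x), np.diff(y))
        speeds.append(
            {
                "track_id": tid,
                "mean_speed_um_min": float(steps.sum() / dt.sum() * 60.0),
                "n_steps": len(steps),
                "net_displacement_um": float(np.hypot(x[-1] - x[0], y[-1] - y[0])),
            }
        )
        paths.append(
            pd.DataFrame(
                {"track_id": tid, "t_s": t, "x_um": x - x[0], "y_um": y - y[0]}
            )
        )
    return pd.DataFrame(speeds), pd.concat(paths, ignore_index=True)


def aspect_ratio_map(
    mask: LabelMask,
    records: pd.DataFrame,
    colormap: str = "viridis",
    ar_range: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, Dict]:
    """Pseudo-color the label image by per-cell aspect ratio.

    Returns an RGB float image (background black) and colorbar metadata
    (colormap name, vmin, vmax) sufficient to decode colors back to AR values
    up to colormap quantization.
    """
    import matplotlib

    missing = set(np.unique(mask.labels[mask.labels > 0])) - set(records["cell_id"])
    if missing:
        raise ParameterError(f"records missing labels: {sorted(missing)}")
    cmap = matplotlib.colormaps[colormap].resampled(256)
    ar = records.set_index("cell_id")["aspect_ratio"]
    if ar_range is None:
        vmin, vmax = float(ar.min()), float(ar.max())
    else:
        vmin, vmax = ar_range
    span = max(vmax - vmin, 1e-12)
    rgb = np.zeros((*mask.labels.shape, 3), dtype=float)
    for cell_id, value in ar.items():
        level = int(round(np.clip((value - vmin) / span, 0, 1) * 255))
        rgb[mask.labels == cell_id] = cmap(level)[:3]
    meta = {"colormap": colormap, "vmin": vmin, "vmax": vmax, "levels": 256}
    return rgb, meta
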