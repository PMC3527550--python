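"""From two-channel fluorescence images to per-cell and per-well uptake.

The chain: rolling-ball background subtraction on the ligand channel,
nuclei segmentation on the nuclei channel, expansion of each nucleus into
a cell region, integration of background-subtracted ligand intensity over
each region, and the per-well median over all cells of all images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, morphology, segmentation

#: default rolling-ball radius, px
DEFAULT_BALL_RADIUS = 25
#: default nucleus-to-cell expansion, px
DEFAULT_EXPANSION = 10
DEFAULT_MIN_AREA = 30


@dataclass
class ImageField:
    """One imaged field: channel-role -> 2-D intensity raster (>= 0)."""

    channels: dict
    source_id: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class CellRecord:
    label: int
    centroid: tuple[float, float]  # (row, col)
    nucleus_area: int
    ligand_intensity: float
    marker_intensity: float | None = None


def rolling_ball_subtract(image: np.ndarray, radius: int = DEFAULT_BALL_RADIUS) -> np.ndarray:
    """Remove smooth background: image minus its grayscale opening.

    The opening with a disk of the given radius is a morphological estimate
    of everything wider than the structuring element — the smooth background
    a rolling-ball filter would fit.  Output is float, clipped at 0, so a
    flat image maps to all zeros and puncta narrower than the disk survive.
    """
    image = np.asarray(image)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(image.shape):
        raise ValueError(f"radius {radius} too large for image {image.shape}")
    background = morphology.opening(image, morphology.disk(radius))
    return np.clip(image.astype(np.float64) - background, 0, None)


def _boundary_gradient_threshold(image: np.ndarray, n_candidates: int = 24) -> float:
    """Threshold maximizing mean gradient magnitude along the mask boundary.

    Candidate thresholds are intensity quantiles; for each, the mean Sobel
    gradient over the boundary pixels of the thresholded mask is scored.
    Falls back to Otsu when no candidate yields a usable boundary.
    """
    grad = filters.sobel(image.astype(np.float64))
    lo, hi = np.quantile(image, [0.05, 0.995])
    if hi <= lo:
        return float(hi)
    candidates = np.linspace(lo, hi, n_candidates)
    best_t, best_score = None, -np.inf
    for t in candidates:
        mask = image > t
        if not mask.any() or mask.all():
            continue
        boundary = mask ^ ndimage.binary_erosion(mask)
        n = boundary.sum()
        if n < 8:
            continue
        score = grad[boundary].mean()
        if score > best_score:
            best_score, best_t = score, t
    if best_t is None:
        return float(filters.threshold_otsu(image))
    return float(best_t)


def segment_nuclei(
    nuclei_channel: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    split_touching: bool = True,
    split_min_distance: int = 14,
) -> np.ndarray:
    """Gradient-thresholded, watershed-split nuclei label mask.

    The intensity threshold is chosen from the image's gradient structure
    (maximal mean boundary gradient, Otsu fallback), small objects are
    dropped, and touching objects are optionally split by a
    distance-transform watershed.  A blank image yields an empty mask.
    """
    image = np.asarray(nuclei_channel, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty raster")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    t = _boundary_gradient_threshold(image)
    mask = ndimage.binary_fill_holes(image > t)
    labels = _drop_small(ndimage.label(mask)[0], min_area)
    if not labels.any():
        return np.zeros(image.shape, dtype=np.int32)
    if split_touching:
        mask = labels > 0
        distance = ndimage.distance_transform_edt(mask)
        smooth = ndimage.gaussian_filter(distance, sigma=2.0)
        # conservative seeding: well-separated distance peaks; a lone convex
        # blob keeps a single seed and is not split
        peaks = feature.peak_local_max(
            smooth, min_distance=split_min_distance, labels=labels, exclude_border=False
        )
        seed_mask = np.zeros(mask.shape, dtype=bool)
        if len(peaks):
            seed_mask[tuple(peaks.T)] = True
        # components that received no peak keep their distance maximum
        seeded = np.unique(labels[seed_mask])
        for lab in np.unique(labels[labels > 0]):
            if lab not in seeded:
                idx = np.unravel_index(np.argmax(np.where(labels == lab, smooth, -1)), mask.shape)
                seed_mask[idx] = True
        seeds, _ = ndimage.label(seed_mask)
        labels = segmentation.watershed(-distance, seeds, mask=mask)
        labels = _drop_small(labels, min_area)
    return _relabel(labels)


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    areas = np.bincount(labels.ravel())
    kill = np.flatnonzero(areas < min_area)
    out = labels.copy()
    out[np.isin(out, kill)] = 0
    return out


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels consecutively from 1, preserving order."""
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def assign_cell_regions(mask: np.ndarray, expansion_radius: int = DEFAULT_EXPANSION) -> np.ndarray:
    """Grow each nucleus label by ``expansion_radius`` px into a cell region.

    Contested pixels go to the nearest nucleus (ties broken by label
    order); regions of distinct nuclei never overlap.  Radius 0 returns
    the mask unchanged.
    """
    if expansion_radius < 0:
        raise ValueError("expansion_radius must be >= 0")
    if expansion_radius == 0:
        return mask.copy()
    return segmentation.expand_labels(mask, distance=expansion_radius)


def quantify_cells(
    field: ImageField,
    regions: np.ndarray,
    ball_radius: int = DEFAULT_BALL_RADIUS,
    nuclei_mask: np.ndarray | None = None,
) -> list[CellRecord]:
    """Integrated background-subtracted ligand intensity per cell region.

    ``regions`` is the cell-region label mask; ``nuclei_mask`` (defaults to
    ``regions``) provides nuclear centroid and area.  A ``marker`` channel,
    if present, is integrated the same way without background subtraction
    (it reports expression level, not puncta).
    """
    regions = np.asarray(regions)
    if regions.shape != field.shape:
        raise ValueError(f"regions shape {regions.shape} != field shape {field.shape}")
    if nuclei_mask is None:
        nuclei_mask = regions
    ligand = rolling_ball_subtract(field.channels["ligand"], ball_radius)
    labels = np.unique(regions[regions > 0])
    if labels.size == 0:
        return []
    sums = ndimage.sum_labels(ligand, regions, labels)
    marker_sums = None
    if "marker" in field.channels:
        marker_sums = ndimage.sum_labels(
            np.asarray(field.channels["marker"], dtype=np.float64), regions, labels
        )
    records = []
    for i, lab in enumerate(labels):
        nuc = nuclei_mask == lab
        area = int(nuc.sum())
        if area > 0:
            rr, cc = np.nonzero(nuc)
            centroid = (float(rr.mean()), float(cc.mean()))
        else:
            rr, cc = np.nonzero(regions == lab)
            centroid = (float(rr.mean()), float(cc.mean()))
        records.append(
            CellRecord(
                label=int(lab),
                centroid=centroid,
                nucleus_area=area,
                ligand_intensity=float(sums[i]),
                marker_intensity=None if marker_sums is None else float(marker_sums[i]),
            )
        )
    return records


def well_median(cells: list[CellRecord]) -> float | None:
    """Median per-cell ligand intensity; None for an empty well (excluded
    downstream as a missing value)."""
    if not cells:
        return None
    return float(np.median([c.ligand_intensity for c in cells]))
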