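"""Partition of stained tissue into virtual cells (v-cells).

The segmentation follows four morphological steps:

1. crop away the empty background frame around the tissue core;
2. build a binary tissue mask by Huang fuzzy thresholding of the minimum
   of the haematoxylin and eosin transmittance channels;
3. detect nuclear seeds as basins of depth >= h in the haematoxylin
   channel (h-concave transform), then remove noise components with a
   binary opening by reconstruction (e erosions);
4. assign every mask pixel to the zone of influence of one seed with a
   marker-controlled watershed, yielding the v-cell label image.

Each v-cell carries the label of its enclosed nucleus, which is what the
feature-extraction stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import reconstruction
from skimage.segmentation import watershed

from .errors import (
    DegenerateThresholdError,
    EmptyPartitionError,
    NoTissueError,
    ParameterError,
)

# 8-connectivity structuring elements
_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class VCellMap:
    """Label image of virtual cells with their paired nuclear seeds.

    ``labels`` tiles the tissue mask with ids 1..n (0 = background);
    ``nuclei`` holds the seed components, each sharing the id of its
    enclosing v-cell.
    """

    labels: np.ndarray
    nuclei: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def areas(self) -> np.ndarray:
        """Pixel area per v-cell id (index 0 -> id 1)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)[1:]


def crop_to_tissue(image: np.ndarray, threshold: int = 200, n_erosions: int = 5):
    """Crop an RGB image to the bounding box of its large stained regions.

    A grey version is thresholded (stained = darker than ``threshold``),
    small specks are removed by opening by reconstruction, and the image
    is cut to the bounding box of the surviving foreground.

    Returns ``(cropped, (row_offset, col_offset))``.
    """
    image = np.asarray(image)
    grey = image.mean(axis=2) if image.ndim == 3 else image.astype(float)
    fg = grey < threshold
    fg = binary_opening_by_reconstruction(fg, n_erosions)
    if not fg.any():
        raise NoTissueError("no stained tissue found above background")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return image[r0:r1, c0:c1], (int(r0), int(c0))


def huang_threshold(grey: np.ndarray) -> int:
    """Huang's fuzzy-entropy global threshold on the 256-bin histogram.

    For every candidate threshold the image is described by fuzzy
    memberships to foreground/background (closer to the class mean ->
    membership closer to 1); the threshold minimising the total Shannon
    fuzziness is returned.  Ties go to the lower threshold.
    """
    grey = np.asarray(grey)
    hist = np.bincount(grey.astype(np.uint8).ravel(), minlength=256).astype(float)
    nz = np.flatnonzero(hist)
    if nz.size < 2:
        raise DegenerateThresholdError("histogram has a single grey level")
    first, last = nz[0], nz[-1]
    levels = np.arange(256, dtype=float)
    # cumulative sums for O(1) class means per candidate threshold
    w = np.cumsum(hist)
    s = np.cumsum(hist * levels)
    total_w, total_s = w[-1], s[-1]
    c = float(last - first)  # membership scale

    best_t, best_ent = first, np.inf
    for t in range(first, last):
        w0 = w[t]
        if w0 == 0 or w0 == total_w:
            continue
        mu0 = s[t] / w0
        mu1 = (total_s - s[t]) / (total_w - w0)
        mu = np.where(levels <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(levels - mu) / c)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -(u * np.log(u) + (1.0 - u) * np.log(1.0 - u))
        ent = np.nan_to_num(ent, nan=0.0)
        val = float(np.sum(hist * ent))
        if val < best_ent:  # strict: ties keep the lower threshold
            best_ent, best_t = val, t
    return int(best_t)


def tissue_mask(stain: np.ndarray) -> np.ndarray:
    """Binary mask of stained tissue from the stain transmittance image.

    Foreground = pixels whose min(haematoxylin, eosin) transmittance is at
    or below Huang's threshold; the residual channel plays no part.
    """
    stain = np.asarray(stain)
    min_he = np.minimum(stain[..., 0], stain[..., 1])
    t = huang_threshold(min_he)
    return min_he <= t


def hconcave(grey: np.ndarray, h: int) -> np.ndarray:
    """h-concave transform: HMIN_h(grey) - grey.

    HMIN_h is the h-minima transform (reconstruction by erosion of
    grey + h over grey); the result is positive exactly inside intensity
    basins, and a basin of depth d is filled by min(d, h).  The image
    border acts as an outlet, not a wall: regions connected to the
    border at their own level (e.g. a flat image) are not basins.
    """
    if not 1 <= h <= 255:
        raise ParameterError(f"h must be in [1, 255], got {h}")
    g = np.asarray(grey, dtype=float)
    lo = float(g.min())
    mask_p = np.pad(g, 1, constant_values=lo)
    seed_p = np.pad(g + h, 1, constant_values=lo)  # border not lifted: drains
    hmin = reconstruction(seed_p, mask_p, method="erosion", footprint=_SQUARE3)
    return hmin[1:-1, 1:-1] - g


def binary_opening_by_reconstruction(mask: np.ndarray, e: int) -> np.ndarray:
    """Remove components that vanish under ``e`` 3x3 erosions; survivors
    keep their exact original shape (reconstruction by dilation)."""
    if e < 0:
        raise ParameterError(f"e must be >= 0, got {e}")
    mask = np.asarray(mask, dtype=bool)
    if e == 0 or not mask.any():
        return mask.copy()
    eroded = mask
    for _ in range(e):
        eroded = ndi.binary_erosion(eroded, structure=_SQUARE3, border_value=0)
    if not eroded.any():
        return np.zeros_like(mask)
    rec = reconstruction(eroded.astype(np.uint8), mask.astype(np.uint8),
                         method="dilation", footprint=_SQUARE3)
    return rec.astype(bool)


def hminima(grey: np.ndarray, h: int) -> np.ndarray:
    """h-minima transform HMIN_h: basins shallower than h are filled and
    disappear; deeper basins become flat plateaus raised by h."""
    return hconcave(grey, h) + np.asarray(grey, dtype=float)


def nuclear_seeds(haem: np.ndarray, mask: np.ndarray, h: int = 30, e: int = 3) -> np.ndarray:
    """Nuclear marker image: regional minima of depth >= h in the
    haematoxylin channel, inside the tissue mask, cleaned by opening by
    reconstruction.

    A basin deeper than h turns, under the h-minima transform, into a
    flat plateau surrounded by strictly higher pixels — the dark
    8-connected region within depth h of the basin bottom.  Those
    plateaus (the regional minima of HMIN_h) are the seeds; basins
    shallower than h merge into their surroundings and yield none, so
    the seed count never grows as h increases.
    """
    from skimage.morphology import local_minima

    hm = hminima(haem, h)
    seeds = local_minima(hm, connectivity=2) & np.asarray(mask, dtype=bool)
    return binary_opening_by_reconstruction(seeds, e)


def partition_vcells(
    mask: np.ndarray,
    seeds: np.ndarray,
    haem: np.ndarray | None = None,
    mode: str = "intensity",
) -> VCellMap:
    """Marker-controlled watershed of the tissue mask into v-cells.

    Every mask pixel is assigned to the zone of influence of exactly one
    8-connected seed component.  ``mode='intensity'`` floods the
    haematoxylin transmittance landscape (dark nuclei are basins);
    ``mode='distance'`` uses pure geodesic influence zones (flooding the
    distance transform to the seeds).  Mask pixels unreachable by
    flooding (mask components without a seed) are assigned to the nearest
    seed region by Euclidean distance, so the labels always tile the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    seeds = np.asarray(seeds, dtype=bool) & mask
    markers, n = ndi.label(seeds, structure=_SQUARE3)
    if n == 0:
        raise EmptyPartitionError("no seeds inside the tissue mask")
    if mode == "intensity":
        if haem is None:
            raise ParameterError("intensity mode requires the haematoxylin channel")
        landscape = np.asarray(haem, dtype=float)
    elif mode == "distance":
        landscape = ndi.distance_transform_edt(~seeds)
    else:
        raise ParameterError(f"unknown watershed mode {mode!r}")
    labels = watershed(landscape, markers=markers, mask=mask, connectivity=2)

    leftover = mask & (labels == 0)
    if leftover.any():
        # nearest-label fill for mask islands that contain no seed
        _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
        labels[leftover] = labels[ir[leftover], ic[leftover]]
    nuclei = np.where(seeds, labels, 0)
    return VCellMap(labels=labels.astype(np.int32), nuclei=nuclei.astype(np.int32))


def segment(
    stain: np.ndarray,
    h: int = 30,
    e: int = 3,
    watershed_mode: str = "intensity",
) -> VCellMap:
    """Full morphological segmentation of a stain image into v-cells."""
    mask = tissue_mask(stain)
    haem = stain[..., 0]
    seeds = nuclear_seeds(haem, mask, h=h, e=e)
    return partition_vcells(mask, seeds, haem=haem, mode=watershed_mode)
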