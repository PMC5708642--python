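"""Per-virtual-cell colour and morphology descriptors.

Each v-cell is described by 63 features: 11 intensity statistics on each
of the three stain transmittance channels (haematoxylin, eosin,
residual), 22 shape descriptors of the v-cell region, and 8 shape
descriptors of its enclosed nuclear marker.  The table is the input to
the clustering ensemble; columns are z-standardised there because the
features mix pixel units, intensities and dimensionless ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from ._shape import nucleus_shape, vcell_shape
from .errors import EmptyRegionError, PairingError
from .segmentation import VCellMap

STAIN_CHANNELS = ("haem", "eosin", "residual")

COLOUR_STAT_NAMES = (
    "mode", "median", "mean", "avgdev", "stddev",
    "min", "max", "variance", "skewness", "kurtosis", "entropy",
)

VCELL_SHAPE_NAMES = (
    "perimeter", "area", "minr", "maxr", "feret", "breadth",
    "chull_perimeter", "chull_area", "aspect_ratio", "circularity",
    "roundness", "area_eq_diameter", "perimeter_eq_diameter",
    "eq_ellipse_area", "compactness", "solidity", "shape", "rfactor",
    "modification_ratio", "sphericity", "arbbox", "rectangularity",
)

NUCLEUS_SHAPE_NAMES = (
    "perimeter", "area", "chull_area", "circularity",
    "solidity", "concavity", "convexity", "shape",
)

#: the 63 feature column names, in table order
FEATURE_COLUMNS = tuple(
    [f"{ch}_{s}" for ch in STAIN_CHANNELS for s in COLOUR_STAT_NAMES]
    + [f"vcell_{s}" for s in VCELL_SHAPE_NAMES]
    + [f"nucleus_{s}" for s in NUCLEUS_SHAPE_NAMES]
)


def colour_stats(values: np.ndarray) -> dict[str, float]:
    """Eleven intensity statistics of one region in one stain channel.

    mode and entropy use the 256-bin histogram of the 8-bit values
    (entropy in bits); skewness and kurtosis are the moment estimators,
    kurtosis as excess, both defined as 0 for constant regions.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise EmptyRegionError("empty region has no colour statistics")
    v = values.astype(float)
    hist = np.bincount(values.astype(np.uint8), minlength=256)
    p = hist[hist > 0] / values.size
    entropy = float(-(p * np.log2(p)).sum())
    mean = float(v.mean())
    var = float(v.var())
    if var > 0:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))
    else:
        skew = kurt = 0.0
    return {
        "mode": float(np.argmax(hist)),
        "median": float(np.median(v)),
        "mean": mean,
        "avgdev": float(np.abs(v - mean).mean()),
        "stddev": float(v.std()),
        "min": float(v.min()),
        "max": float(v.max()),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
    }


def build_feature_table(vcells: VCellMap, stain: np.ndarray) -> pd.DataFrame:
    """One row per v-cell: 33 colour + 22 v-cell shape + 8 nucleus shape.

    Rows are ordered by ascending v-cell id; the id is kept as the index.
    """
    labels, nuclei = vcells.labels, vcells.nuclei
    n = vcells.n_cells
    stain = np.asarray(stain)
    vc_slices = ndi.find_objects(labels)
    nuc_slices = ndi.find_objects(nuclei)
    rows = []
    for vid in range(1, n + 1):
        sl = vc_slices[vid - 1]
        if sl is None:
            raise PairingError(f"v-cell id {vid} has no pixels")
        region = labels[sl] == vid
        row: dict[str, float] = {}
        for c, ch in enumerate(STAIN_CHANNELS):
            vals = stain[sl][..., c][region]
            for name, val in colour_stats(vals).items():
                row[f"{ch}_{name}"] = val
        for name, val in vcell_shape(region).items():
            row[f"vcell_{name}"] = val
        nsl = nuc_slices[vid - 1] if vid - 1 < len(nuc_slices) else None
        if nsl is None:
            raise PairingError(f"v-cell {vid} has no paired nucleus")
        nregion = nuclei[nsl] == vid
        for name, val in nucleus_shape(nregion).items():
            row[f"nucleus_{name}"] = val
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, n + 1, name="vcell_id"))
    return table[list(FEATURE_COLUMNS)]


def standardise(table: pd.DataFrame) -> np.ndarray:
    """Z-score each column; constant columns map to 0."""
    x = table.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd
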