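"""Low-level shape geometry for binary regions.

All descriptors operate on a single 8-connected binary region given as a
boolean array (a regionprops-style crop).  Conventions:

* area = pixel count;
* perimeter = length of the boundary polygon through the centres of the
  boundary pixels (Moore trace, diagonal steps weighted sqrt(2));
* the convex hull is built from the corners of the boundary pixels, so
  the hull polygon always contains the whole pixel region (hull area >=
  area, hence solidity <= 1);
* MinR/MaxR are measured from the binary centre of mass to the nearest
  boundary pixel / farthest region pixel.

A one-pixel region is treated as a unit square (perimeter 4, area 1);
ratios with a zero denominator are reported as 0 to keep downstream
clustering free of NaNs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from .errors import EmptyRegionError

# clockwise Moore neighbourhood, starting East
_DIRS = np.array([(0, 1), (1, 1), (1, 0), (1, -1),
                  (0, -1), (-1, -1), (-1, 0), (-1, 1)])
_STEP_LEN = np.array([1.0, np.sqrt(2.0)] * 4)


def boundary_walk(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixel walk (Moore tracing, Jacob stopping).

    Returns the closed walk as an (m, 2) array of (row, col) pixel
    coordinates; thin appendages are traversed twice, as in any
    boundary-following perimeter.  A single pixel returns itself.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("empty region")
    padded = np.pad(mask, 1)
    rs, cs = np.nonzero(padded)
    start = (int(rs[0]), int(cs[0]))  # topmost-leftmost
    if len(rs) == 1:
        return np.array([start]) - 1

    p, backtrack = start, 4  # pretend we arrived from the West
    walk = [p]
    first_move = None
    while True:
        for k in range(8):
            d = (backtrack + 1 + k) % 8
            nb = (p[0] + _DIRS[d][0], p[1] + _DIRS[d][1])
            if padded[nb]:
                break
        else:  # isolated pixel cluster exhausted (cannot happen for >1 px)
            break
        if first_move is None:
            first_move = (p, d)
        elif p == start and (p, d) == first_move:
            break  # about to repeat the initial move: loop closed
        walk.append(nb)
        backtrack = (d + 4) % 8
        p = nb
    return np.asarray(walk[:-1] if len(walk) > 1 else walk) - 1


def polygon_perimeter(mask: np.ndarray) -> float:
    """Length of the closed boundary-pixel polygon (1-pixel region -> 4)."""
    walk = boundary_walk(mask)
    if len(walk) == 1:
        return 4.0
    closed = np.vstack([walk, walk[:1]])
    steps = np.diff(closed, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def pixel_corners(mask: np.ndarray) -> np.ndarray:
    """Corner points of the region's boundary pixels (for hull building)."""
    mask = np.asarray(mask, dtype=bool)
    inner = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    br, bc = np.nonzero(mask & ~inner)
    offs = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    pts = (np.stack([br, bc], axis=1)[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return np.unique(pts, axis=0)


def convex_hull_polygon(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices (counter-clockwise) of the pixel-corner cloud."""
    pts = pixel_corners(mask)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _polygon_perimeter(verts: np.ndarray) -> float:
    d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def feret_breadth(hull_verts: np.ndarray) -> tuple[float, float]:
    """Maximum caliper length and the largest extent perpendicular to it."""
    v = hull_verts
    if len(v) == 1:
        return 0.0, 0.0
    diff = v[:, None, :] - v[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    feret = float(np.sqrt(d2[i, j]))
    if feret == 0.0:
        return 0.0, 0.0
    axis = (v[j] - v[i]) / feret
    perp = np.array([-axis[1], axis[0]])
    proj = v @ perp
    breadth = float(proj.max() - proj.min())
    return feret, breadth


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def region_geometry(mask: np.ndarray) -> dict[str, float]:
    """All primitive geometric measurements of one region."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("empty region")
    area = float(mask.sum())
    perim = polygon_perimeter(mask)
    hull = convex_hull_polygon(mask)
    chull_perim = _polygon_perimeter(hull)
    chull_area = _polygon_area(hull)
    feret, breadth = feret_breadth(hull)

    rr, cc = np.nonzero(mask)
    centroid = np.array([rr.mean(), cc.mean()])
    pix = np.stack([rr, cc], axis=1).astype(float)
    dists = np.hypot(*(pix - centroid).T)
    max_r = float(dists.max())
    inner = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    bpix = np.stack(np.nonzero(mask & ~inner), axis=1).astype(float)
    min_r = float(np.hypot(*(bpix - centroid).T).min())
    return {
        "area": area,
        "perimeter": perim,
        "chull_perimeter": chull_perim,
        "chull_area": chull_area,
        "feret": feret,
        "breadth": breadth,
        "min_r": min_r,
        "max_r": max_r,
    }


def vcell_shape(mask: np.ndarray) -> dict[str, float]:
    """The 22 morphological descriptors of a virtual cell."""
    g = region_geometry(mask)
    area, perim = g["area"], g["perimeter"]
    feret, breadth = g["feret"], g["breadth"]
    ar_bbox = feret * breadth
    return {
        "perimeter": perim,
        "area": area,
        "minr": g["min_r"],
        "maxr": g["max_r"],
        "feret": feret,
        "breadth": breadth,
        "chull_perimeter": g["chull_perimeter"],
        "chull_area": g["chull_area"],
        "aspect_ratio": _safe_div(feret, breadth),
        "circularity": _safe_div(4.0 * np.pi * area, perim ** 2),
        "roundness": _safe_div(4.0 * area, np.pi * feret ** 2),
        "area_eq_diameter": float(np.sqrt(4.0 / np.pi * area)),
        "perimeter_eq_diameter": perim / np.pi,
        "eq_ellipse_area": np.pi * feret * breadth / 4.0,
        "compactness": _safe_div(np.sqrt(4.0 / np.pi * area), feret),
        "solidity": _safe_div(area, g["chull_area"]),
        "shape": _safe_div(perim ** 2, area),
        "rfactor": _safe_div(g["chull_perimeter"], feret * np.pi),
        "modification_ratio": _safe_div(2.0 * g["min_r"], feret),
        "sphericity": _safe_div(g["min_r"], g["max_r"]),
        "arbbox": ar_bbox,
        "rectangularity": _safe_div(area, ar_bbox),
    }


def nucleus_shape(mask: np.ndarray) -> dict[str, float]:
    """The 8 morphological descriptors of a nuclear marker."""
    g = region_geometry(mask)
    area, perim = g["area"], g["perimeter"]
    return {
        "perimeter": perim,
        "area": area,
        "chull_area": g["chull_area"],
        "circularity": _safe_div(4.0 * np.pi * area, perim ** 2),
        "solidity": _safe_div(area, g["chull_area"]),
        "concavity": g["chull_area"] - area,
        "convexity": _safe_div(g["chull_perimeter"], perim),
        "shape": _safe_div(perim ** 2, area),
    }
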