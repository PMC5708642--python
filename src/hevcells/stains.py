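"""Colour deconvolution of H&E images into stain transmittance channels.

Brightfield H&E images mix the absorbances of haematoxylin (nuclei) and
eosin (cytoplasm/stroma) subtractively following the Beer-Lambert law.
Given the RGB absorbance direction of each dye, the per-pixel optical
densities can be unmixed by solving a 3x3 linear system, yielding one
transmittance channel per stain.  The three unmixed channels (haematoxylin,
eosin, residual) are re-packed into a single 8-bit "stain image" whose
R/G/B planes hold per-stain light transmittance rather than colour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidStainVectorsError

#: grey levels added before the log to bound optical density on saturated pixels
OD_EPSILON = 1.0

# Standard published H&E absorbance directions (unit RGB vectors).
_HAEM = (0.650, 0.704, 0.286)
_EOSIN = (0.072, 0.990, 0.105)


@dataclass(frozen=True)
class StainVectors:
    """Unit absorbance directions for haematoxylin, eosin and the residual.

    The residual direction completes the basis for two-dye stains; by
    construction it is orthogonal to both dye vectors.
    """

    matrix: np.ndarray  # rows: H, E, residual

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidStainVectorsError(f"expected 3x3 stain matrix, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise InvalidStainVectorsError("zero-length stain vector")
        m = m / norms[:, None]
        if abs(np.linalg.det(m)) < 1e-8:
            raise InvalidStainVectorsError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def default_he_vectors() -> StainVectors:
    """Standard H&E basis with an orthogonal residual channel.

    The residual is the normalised cross product of the haematoxylin and
    eosin directions, i.e. the absorbance direction explained by neither dye.
    """
    h = np.array(_HAEM) / np.linalg.norm(_HAEM)
    e = np.array(_EOSIN) / np.linalg.norm(_EOSIN)
    r = np.cross(h, e)
    r /= np.linalg.norm(r)
    return StainVectors(np.stack([h, e, r]))


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected HxWx3 RGB image, got shape {image.shape}")
    return image


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Per-channel optical density, OD = -log((v + eps)/255)."""
    v = np.asarray(image, dtype=float)
    return -np.log((v + OD_EPSILON) / 255.0)


def od_to_transmittance(density: np.ndarray) -> np.ndarray:
    """Transmittance on the 8-bit scale, 255*exp(-d)."""
    return 255.0 * np.exp(-np.asarray(density, dtype=float))


def deconvolve_densities(image: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Per-pixel stain densities (float, H/E/residual planes), negatives clipped."""
    image = _check_rgb(image)
    if vectors is None:
        vectors = default_he_vectors()
    od = rgb_to_od(image)
    dens = od @ vectors.inverse  # solves d @ M = od per pixel
    return np.clip(dens, 0.0, None)


def deconvolve(image: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Unmix an 8-bit RGB H&E image into the 8-bit stain transmittance image.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
        Background-corrected transmitted-light RGB image.
    vectors : StainVectors, optional
        Absorbance basis; defaults to the standard H&E basis.

    Returns
    -------
    (H, W, 3) uint8 array
        Channels hold the light transmittance of haematoxylin, eosin and
        the residual, each in [0, 255].
    """
    dens = deconvolve_densities(image, vectors)
    trans = od_to_transmittance(dens)
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)


def compose(densities: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Forward Beer-Lambert model: per-stain densities -> 8-bit RGB image.

    The inverse of :func:`deconvolve` up to 8-bit quantisation; used both
    by the synthetic image generator and as the round-trip oracle.
    """
    if vectors is None:
        vectors = default_he_vectors()
    dens = np.asarray(densities, dtype=float)
    od = dens @ vectors.matrix
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
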