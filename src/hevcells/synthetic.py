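"""Synthetic H&E-like tissue images and planted feature datasets.

The tissue generator emulates the structure the segmentation method
exploits: a bright background, a roughly circular tissue core split into
two blobby compartments, and dark elliptical nuclei — denser and rounder
in the epithelium, sparser and more elongated in the stroma — embedded
in compartment-specific diffuse haematoxylin/eosin uptake.  Per-stain
density fields are composed to RGB through the forward Beer-Lambert
model with additive Gaussian noise, and the exact three-class pixel gold
standard and nucleus centres are returned alongside the image.

Nuclei are placed by dart-throwing with a minimum spacing (Poisson-disc
style) so that neighbouring nuclei do not merge into one seed, which the
segmentation method does not claim to split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .stains import compose, default_he_vectors


@dataclass(frozen=True)
class CompartmentSpec:
    """Stain and nuclear statistics of one tissue compartment."""

    nucleus_density: float          # nuclei per 10^4 px^2
    nucleus_radius: tuple[float, float]   # minor semi-axis range, px
    eccentricity: tuple[float, float]     # major/minor axis ratio range
    haem_density: float             # diffuse cytoplasm H optical density
    eosin_density: float            # diffuse E optical density
    min_spacing: float              # centre-to-centre exclusion radius, px


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic tissue core."""

    size: int = 512
    core_radius_frac: float = 0.46
    epithelium: CompartmentSpec = field(default_factory=lambda: CompartmentSpec(
        nucleus_density=18.0, nucleus_radius=(4.5, 6.0), eccentricity=(1.0, 1.25),
        haem_density=0.45, eosin_density=0.25, min_spacing=15.0))
    stroma: CompartmentSpec = field(default_factory=lambda: CompartmentSpec(
        nucleus_density=8.0, nucleus_radius=(4.5, 5.2), eccentricity=(1.5, 2.2),
        haem_density=0.12, eosin_density=0.55, min_spacing=21.0))
    nucleus_haem_density: float = 1.3   # H density inside nuclei
    background_density: float = 0.02    # residual haze outside the core
    noise_sd: float = 2.0               # Gaussian RGB noise, grey levels
    compartment_smoothness: float = 0.12  # blob scale as a fraction of size
    rng_seed: int = 0


def _compartment_masks(spec: SyntheticSpec, rng: np.random.Generator):
    """Tissue disc split into two blobby, disjoint compartments."""
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    core = (yy - c) ** 2 + (xx - c) ** 2 <= (spec.core_radius_frac * n) ** 2
    fieldv = ndi.gaussian_filter(rng.standard_normal((n, n)),
                                 sigma=spec.compartment_smoothness * n)
    cut = np.median(fieldv[core])
    epi = core & (fieldv > cut)
    stroma = core & ~epi
    return core, epi, stroma


def _place_nuclei(region: np.ndarray, comp: CompartmentSpec,
                  taken: list[np.ndarray], rng: np.random.Generator,
                  margin: float) -> np.ndarray:
    """Dart-throwing placement inside ``region`` with global min spacing."""
    interior = ndi.distance_transform_edt(region) > margin
    coords = np.argwhere(interior)
    if len(coords) == 0:
        return np.empty((0, 2))
    target = int(round(comp.nucleus_density * 1e-4 * region.sum()))
    accepted: list[np.ndarray] = []
    existing = np.vstack(taken) if taken else np.empty((0, 2))
    attempts = 0
    while len(accepted) < target and attempts < 40 * max(target, 1):
        attempts += 1
        p = coords[rng.integers(len(coords))].astype(float)
        pool = np.vstack([existing] + [np.array(accepted)]) if accepted else existing
        if len(pool) and np.min(np.hypot(*(pool - p).T)) < comp.min_spacing:
            continue
        accepted.append(p)
    return np.array(accepted) if accepted else np.empty((0, 2))


def _paint_ellipse(canvas: np.ndarray, centre, a: float, b: float,
                   theta: float, value: float):
    """Set ``canvas`` to max(canvas, value) inside a rotated ellipse."""
    r0, c0 = centre
    ext = int(np.ceil(max(a, b))) + 1
    rlo, rhi = max(int(r0) - ext, 0), min(int(r0) + ext + 1, canvas.shape[0])
    clo, chi = max(int(c0) - ext, 0), min(int(c0) + ext + 1, canvas.shape[1])
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    dy, dx = yy - r0, xx - c0
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    patch = canvas[rlo:rhi, clo:chi]
    patch[inside] = np.maximum(patch[inside], value)


def generate_tissue_image(spec: SyntheticSpec = SyntheticSpec()):
    """Render one synthetic H&E core.

    Returns ``(rgb_image, gold_pixel_map, nucleus_centres)`` where the
    gold map uses 0 = background, 1 = epithelium, 2 = stroma and the
    centres array carries (row, col, compartment_class) per nucleus.
    The output is a deterministic function of the spec (seed included).
    """
    rng = np.random.default_rng(spec.rng_seed)
    core, epi, stroma = _compartment_masks(spec, rng)
    if (epi & stroma).any():
        raise ParameterError("compartments overlap")
    n = spec.size

    haem = np.full((n, n), 0.0)
    eosin = np.full((n, n), 0.0)
    haem[epi] = spec.epithelium.haem_density
    eosin[epi] = spec.epithelium.eosin_density
    haem[stroma] = spec.stroma.haem_density
    eosin[stroma] = spec.stroma.eosin_density
    haem[~core] = spec.background_density
    eosin[~core] = spec.background_density

    taken: list[np.ndarray] = []
    centres = []
    for cls, (mask, comp) in enumerate(
            [(epi, spec.epithelium), (stroma, spec.stroma)], start=1):
        max_major = comp.nucleus_radius[1] * comp.eccentricity[1]
        pts = _place_nuclei(mask, comp, taken, rng, margin=max_major + 2.0)
        if len(pts):
            taken.append(pts)
        for (r, c) in pts:
            b = rng.uniform(*comp.nucleus_radius)
            ecc = rng.uniform(*comp.eccentricity)
            theta = rng.uniform(0, np.pi)
            _paint_ellipse(haem, (r, c), b * ecc, b, theta,
                           spec.nucleus_haem_density)
            centres.append((r, c, cls))

    densities = np.stack([haem, eosin, np.zeros_like(haem)], axis=-1)
    rgb = compose(densities, default_he_vectors()).astype(float)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    gold = np.zeros((n, n), dtype=np.uint8)
    gold[epi] = 1
    gold[stroma] = 2
    return rgb, gold, np.array(centres).reshape(-1, 3)


def generate_planted_features(n: int, k: int = 2, separation: float = 5.0,
                              noise_sd: float = 1.0, rng_seed: int = 0,
                              n_features: int = 63):
    """Gaussian planted clusters in feature space.

    Cluster centroids sit ``separation * noise_sd`` apart along a random
    direction; points scatter isotropically with ``noise_sd``.  Returns
    ``(X, labels)`` with X of shape (n, n_features).
    """
    if n < 2 * k:
        raise ParameterError(f"need n >= {2 * k}, got {n}")
    rng = np.random.default_rng(rng_seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    labels = np.arange(n) % k
    offsets = (np.arange(k) - (k - 1) / 2.0) * separation * noise_sd
    x = rng.normal(0.0, noise_sd, (n, n_features))
    x += offsets[labels][:, None] * direction[None, :]
    order = rng.permutation(n)
    return x[order], labels[order]
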