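"""Synthetic scenes and a location-aware noisy predictor.

Stands in for a stained-tissue dataset plus a trained segmentation network
so the full stitching benchmark runs self-contained.  Two pieces:

* :func:`generate_scene` renders nuclei-like elliptical blobs on a flat
  background and labels every pixel as one of three classes — background,
  object, or object edge (a thin ring on the inside of each blob boundary).
* :func:`noisy_edge_predictor` wraps the ground truth as a per-patch
  predictor whose additive noise grows toward the patch borders, emulating
  the well-documented degradation of CNN predictions near patch edges and
  corners.  Noise is drawn independently per patch origin, so overlapping
  patches disagree exactly where their predictions are least reliable —
  the regime in which window weighting helps and plain averaging can hurt.

Everything is driven by integer seeds: the same seed reproduces the same
scene, and the predictor derives an independent, reproducible stream per
(seed, origin) so its output is a pure function of the patch location.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import draw

from .reconstruct import DEFAULT_CLASS_NAMES, Predictor
from .tiling import PatchGrid

__all__ = [
    "SceneSpec",
    "ArtefactProfile",
    "generate_scene",
    "label_scene",
    "noisy_edge_predictor",
    "DEFAULT_CLASS_NAMES",
]

# Rendered intensity per class (background, object, object_edge).
_CLASS_INTENSITY = np.array([0.1, 0.8, 0.5])
_IMAGE_NOISE_SIGMA = 0.02
_PLACEMENT_ATTEMPTS = 100


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of a synthetic 3-class nuclei scene.

    Defaults are the benchmark's reference geometry: a 1024x1024 image
    holding 120 non-overlapping elliptical blobs with semi-axes drawn from
    ``radius_range`` (pixels) and a 2-pixel object-edge band.
    """

    height: int = 1024
    width: int = 1024
    n_blobs: int = 120
    radius_range: tuple[float, float] = (8.0, 20.0)
    edge_band: int = 2
    seed: int = 0


@dataclass(frozen=True)
class ArtefactProfile:
    """Border-localised predictor noise.

    The per-pixel noise standard deviation is
    ``base_noise + edge_noise * falloff(d)`` where ``d`` in [0, 1] is the
    pixel's distance to the nearest patch border, normalised so the patch
    centre has ``d = 1``.  ``falloff`` must be non-increasing and defaults
    to ``(1 - d)**2``: full extra noise on the border ring, none at the
    centre, and corner neighbourhoods stay noisy along both axes.
    """

    base_noise: float = 0.02
    edge_noise: float = 0.48
    falloff: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_noise < 0 or self.edge_noise < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.falloff is not None:
            d = np.linspace(0.0, 1.0, 129)
            f = np.asarray(self.falloff(d), dtype=np.float64)
            if f.shape != d.shape or not np.all(np.isfinite(f)) or np.any(f < 0):
                raise ValueError("falloff must map [0, 1] to finite non-negatives")
            if np.any(np.diff(f) > 1e-12):
                raise ValueError(
                    "falloff must be non-increasing: noise may not grow with "
                    "distance from the patch border"
                )

    def sigma_map(self, patch: int) -> np.ndarray:
        """Per-pixel noise sigma for a ``patch``-sized square."""
        k = np.arange(patch, dtype=np.float64)
        axis = np.minimum(k, patch - 1 - k)
        dist = np.minimum(axis[:, None], axis[None, :])
        denom = max(patch / 2.0 - 1.0, 1.0)
        d = np.clip(dist / denom, 0.0, 1.0)
        f = self.falloff(d) if self.falloff is not None else (1.0 - d) ** 2
        return self.base_noise + self.edge_noise * np.asarray(f, dtype=np.float64)


def label_scene(object_mask: np.ndarray, edge_band: int) -> np.ndarray:
    """Classify blob pixels into object (1) / object-edge (2) over background (0).

    The object-edge class is the band of object pixels whose Euclidean
    distance to the background is at most ``edge_band`` (the outermost
    object pixel has distance 1, so ``edge_band = 2`` marks a two-pixel ring).
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    labels = np.zeros(object_mask.shape, dtype=np.uint8)
    labels[object_mask] = 1
    if edge_band > 0 and object_mask.any():
        dist = ndimage.distance_transform_edt(object_mask)
        labels[object_mask & (dist <= edge_band)] = 2
    return labels


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene and its one-hot ground truth.

    Returns ``(image, ground_truth)``: a (H, W) float image in [0, 1] —
    class intensities plus mild i.i.d. Gaussian noise — and a (H, W, 3)
    one-hot map over (background, object, object_edge).  Blobs are
    non-overlapping, non-degenerate ellipses kept ``edge_band + 2`` pixels
    clear of the image border; each is retried a bounded number of times
    and an overfull scene is rejected.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = int(spec.height), int(spec.width)
    r_lo, r_hi = spec.radius_range
    if not (2.0 <= r_lo <= r_hi):
        raise ValueError(f"radius_range must satisfy 2 <= lo <= hi; got {spec.radius_range}")
    margin = spec.edge_band + 2
    if min(h, w) <= 2 * (margin + r_hi):
        raise ValueError(
            f"radius_range {spec.radius_range} does not fit a {h}x{w} image "
            f"with a {margin}-pixel border margin"
        )
    occupied = np.zeros((h, w), dtype=bool)
    for blob in range(spec.n_blobs):
        for _ in range(_PLACEMENT_ATTEMPTS):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            theta = rng.uniform(0.0, np.pi)
            reach = max(a, b)
            cy = rng.uniform(margin + reach, h - 1 - margin - reach)
            cx = rng.uniform(margin + reach, w - 1 - margin - reach)
            rr, cc = draw.ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
            if rr.size == 0 or occupied[rr, cc].any():
                continue
            occupied[rr, cc] = True
            break
        else:
            raise RuntimeError(
                f"could not place blob {blob + 1}/{spec.n_blobs} after "
                f"{_PLACEMENT_ATTEMPTS} attempts; the scene is too crowded "
                f"for the requested radius_range"
            )
    labels = label_scene(occupied, spec.edge_band)
    ground_truth = np.eye(len(DEFAULT_CLASS_NAMES))[labels]
    image = _CLASS_INTENSITY[labels] + rng.normal(0.0, _IMAGE_NOISE_SIGMA, (h, w))
    return np.clip(image, 0.0, 1.0), ground_truth


def noisy_edge_predictor(
    ground_truth: np.ndarray, grid: PatchGrid, profile: ArtefactProfile
) -> Predictor:
    """Predictor emitting the ground truth corrupted by border-heavy noise.

    For the patch at a given origin the ground-truth one-hot probabilities
    are perturbed with additive Gaussian noise of per-pixel sigma
    ``profile.sigma_map``, truncated at zero and renormalised to the
    probability simplex.  Noise is an independent, reproducible stream per
    (profile.seed, origin): calling the predictor twice at the same origin
    returns identical output, and overlapping patches disagree near their
    borders.  With a zero-noise profile the predictor is exact.
    """
    gt = np.asarray(ground_truth, dtype=np.float64)
    if gt.ndim != 3 or gt.shape[2] < 2:
        raise ValueError(
            f"ground truth must be (H, W, C>=2) class scores; got shape {gt.shape}"
        )
    patch = grid.patch
    if gt.shape[0] < patch or gt.shape[1] < patch:
        raise ValueError("ground truth is smaller than the grid's patch size")
    sigma = profile.sigma_map(patch)[:, :, None]
    exact = float(sigma.max()) == 0.0
    n_classes = gt.shape[2]

    def predict(patch_pixels: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
        r, c = int(origin[0]), int(origin[1])
        if r < 0 or c < 0 or r + patch > gt.shape[0] or c + patch > gt.shape[1]:
            raise ValueError(
                f"patch origin {origin} falls outside the simulated ground truth"
            )
        tile = gt[r : r + patch, c : c + patch]
        if exact:
            return tile.copy()
        rng = np.random.default_rng(np.random.SeedSequence([int(profile.seed), r, c]))
        noisy = np.clip(tile + rng.standard_normal(tile.shape) * sigma, 0.0, None)
        total = noisy.sum(axis=2, keepdims=True)
        return np.where(total > 0, noisy / np.where(total == 0, 1.0, total), 1.0 / n_classes)

    return predict
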