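"""Overlap-add reconstruction of per-patch predictions.

The pipeline: extract overlapping patches at half-patch stride, run a
pluggable per-patch predictor on each, multiply each prediction by the
window variant matching the patch's position (interior / edge / corner),
and sum everything at its absolute location.  Because the window variants
form a partition of unity, no division follows — the output is already a
properly weighted average that suppresses each patch's unreliable border
pixels.

A *predictor* is any callable ``predictor(patch, origin) -> (I, I, C)``
taking the raw image patch and its (row, col) origin and returning a
per-class score patch of the same spatial extent (a 2-D return is treated
as a single channel).  The origin lets location-aware predictors (such as
the simulator in :mod:`winstitch.simulate`) look up their context; plain
predictors simply ignore it.

Baselines: ``reconstruct_no_overlap`` concatenates non-overlapping tiles
(``n*m`` predictor calls versus ``(2n-1)*(2m-1)`` for the windowed path),
and ``reconstruct_average`` is the windowed path with the flat average
window.  ``reconstruct_pyramidal`` handles the non-partitioning pyramidal
window, which requires dividing by the assembled weight field.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .tiling import AxisRole, pad_to_grid, plan_grid
from .windows import WindowKind, assemble_window_field, make_window_2d, window_for_role

__all__ = [
    "METHODS",
    "DEFAULT_CLASS_NAMES",
    "Predictor",
    "identity_predictor",
    "reconstruct",
    "reconstruct_windowed",
    "reconstruct_no_overlap",
    "reconstruct_average",
    "reconstruct_pyramidal",
]

#: Channel semantics of the default 3-class segmentation output.
DEFAULT_CLASS_NAMES = ("background", "object", "object_edge")

#: All reconstruction methods, in the benchmark's canonical order.
METHODS = ("no_overlap", "average", "pyramidal", "hann", "bartlett_hann", "triangular")

Predictor = Callable[[np.ndarray, tuple[int, int]], np.ndarray]


def identity_predictor(patch: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Return the input patch unchanged (useful for geometry checks)."""
    return patch


def _validated_prediction(
    out: object, patch: int, origin: tuple[int, int]
) -> np.ndarray:
    out = np.asarray(out, dtype=np.float64)
    if out.ndim == 2:
        out = out[..., None]
    if out.ndim != 3 or out.shape[:2] != (patch, patch):
        raise ValueError(
            f"predictor returned shape {out.shape} for the {patch}x{patch} "
            f"patch at origin {origin}"
        )
    if not np.all(np.isfinite(out)):
        raise ValueError(
            f"predictor returned non-finite values for the patch at origin {origin}"
        )
    return out


def _accumulate_windowed(
    image: np.ndarray,
    predictor: Predictor,
    patch: int,
    window_of,  # (vert, horz) axis roles -> (patch, patch) weights
) -> tuple[np.ndarray, "CropRecord"]:
    padded, crop = pad_to_grid(image, patch)
    grid = plan_grid(padded.shape[0], padded.shape[1], patch)
    out: np.ndarray | None = None
    cache: dict[tuple[AxisRole, AxisRole], np.ndarray] = {}
    for (r, c), axes in zip(grid.origins, grid.axis_roles):
        pred = _validated_prediction(
            predictor(padded[r : r + patch, c : c + patch], (r, c)), patch, (r, c)
        )
        if out is None:
            out = np.zeros((*padded.shape[:2], pred.shape[2]), dtype=np.float64)
        elif pred.shape[2] != out.shape[2]:
            raise ValueError(
                f"predictor changed its channel count at origin {(r, c)}: "
                f"{pred.shape[2]} != {out.shape[2]}"
            )
        if axes not in cache:
            cache[axes] = window_of(axes)
        out[r : r + patch, c : c + patch] += cache[axes][:, :, None] * pred
    assert out is not None
    return out, crop


def reconstruct_windowed(
    image: np.ndarray,
    predictor: Predictor,
    kind: WindowKind | str = WindowKind.HANN,
    patch: int = 128,
    *,
    strict_paper: bool = False,
) -> np.ndarray:
    """Windowed overlap-add reconstruction for a separable window kind.

    Returns an (H, W, C) float64 score map with the extent of the input
    image (non-multiple extents are reflect-padded internally and cropped
    back).  The predictor is invoked once per overlapping patch, i.e.
    ``(2n - 1) * (2m - 1)`` times for an n-by-m-patch image.
    """
    kind = WindowKind(kind)
    if kind is WindowKind.PYRAMIDAL:
        raise ValueError(
            "the pyramidal window does not partition unity; use "
            "reconstruct_pyramidal, which renormalises"
        )
    out, crop = _accumulate_windowed(
        np.asarray(image),
        predictor,
        patch,
        lambda axes: window_for_role(
            kind, axes, patch, patch, strict_paper=strict_paper
        ).weights,
    )
    return crop.crop(out)


def reconstruct_no_overlap(
    image: np.ndarray, predictor: Predictor, patch: int = 128
) -> np.ndarray:
    """Baseline: non-overlapping tiles, straight concatenation (n*m calls)."""
    padded, crop = pad_to_grid(np.asarray(image), patch)
    out: np.ndarray | None = None
    for r in range(0, padded.shape[0], patch):
        for c in range(0, padded.shape[1], patch):
            pred = _validated_prediction(
                predictor(padded[r : r + patch, c : c + patch], (r, c)), patch, (r, c)
            )
            if out is None:
                out = np.zeros((*padded.shape[:2], pred.shape[2]), dtype=np.float64)
            elif pred.shape[2] != out.shape[2]:
                raise ValueError(
                    f"predictor changed its channel count at origin {(r, c)}: "
                    f"{pred.shape[2]} != {out.shape[2]}"
                )
            out[r : r + patch, c : c + patch] = pred
    assert out is not None
    return crop.crop(out)


def reconstruct_average(
    image: np.ndarray, predictor: Predictor, patch: int = 128
) -> np.ndarray:
    """Overlapping patches combined with the flat average window.

    Interior pixels receive the plain mean of the four covering predictions;
    the edge/corner variants keep the total weight at 1 near image borders.
    """
    return reconstruct_windowed(image, predictor, WindowKind.AVERAGE, patch)


def reconstruct_pyramidal(
    image: np.ndarray,
    predictor: Predictor,
    patch: int = 128,
    *,
    ring_fallback: bool = True,
) -> np.ndarray:
    """Overlap-add with the pyramidal window plus its renormalisation step.

    The interior pyramidal window is applied at every patch position and the
    accumulated output is divided pixel-wise by the assembled window field.
    The window is zero on every patch's border ring, so the outermost image
    ring accumulates zero total weight: with ``ring_fallback`` those pixels
    are filled from the nearest positively-weighted pixel (with a warning);
    otherwise they are reported as an error.
    """
    weights = make_window_2d(WindowKind.PYRAMIDAL, patch, patch).weights
    out, crop = _accumulate_windowed(
        np.asarray(image), predictor, patch, lambda axes: weights
    )
    field = assemble_window_field(
        WindowKind.PYRAMIDAL, out.shape[0], out.shape[1], patch
    )
    zero = field < 1e-9
    result = out / np.where(zero, 1.0, field)[:, :, None]
    if zero.any():
        if not ring_fallback:
            raise ValueError(
                f"{int(zero.sum())} pixels received zero total pyramidal "
                f"window weight (outer image ring); enable ring_fallback to "
                f"fill them from their nearest weighted neighbour"
            )
        warnings.warn(
            f"pyramidal reconstruction: {int(zero.sum())} zero-weight pixels "
            f"on the outer image ring filled from nearest weighted neighbours",
            stacklevel=2,
        )
        nearest = ndimage.distance_transform_edt(
            zero, return_distances=False, return_indices=True
        )
        result = result[nearest[0], nearest[1]]
    return crop.crop(result)


def reconstruct(
    image: np.ndarray,
    predictor: Predictor,
    method: str = "hann",
    patch: int = 128,
) -> np.ndarray:
    """Dispatch on a method name from :data:`METHODS`."""
    if method == "no_overlap":
        return reconstruct_no_overlap(image, predictor, patch)
    if method == "average":
        return reconstruct_average(image, predictor, patch)
    if method == "pyramidal":
        return reconstruct_pyramidal(image, predictor, patch)
    if method in ("hann", "bartlett_hann", "triangular"):
        return reconstruct_windowed(image, predictor, method, patch)
    raise ValueError(f"unknown reconstruction method {method!r}; choose from {METHODS}")
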