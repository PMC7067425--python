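"""1-D and 2-D window functions for seam-free patch recombination.

A window is a non-negative weight grid the size of a patch.  When the
window-weighted predictions of overlapping patches (half-patch stride) are
summed at their absolute positions, a window family that forms a *partition
of unity* — all tiled windows summing to exactly 1 at every pixel — rebuilds
the image without any post-hoc renormalisation, while strongly down-weighting
each patch's border pixels where CNN predictions are least reliable.

Separable windows are built as the outer product ``W(i, j) = w(i) * w(j)``
of a 1-D profile ``w``.  The periodic convention (denominator ``I``, not
``I - 1``) is used throughout: only the periodic form tiles to a constant at
50% overlap.  The 1-D profiles, with ``i = 0 .. I-1``:

===============  =====================================================
average          ``w(i) = 1/2``
hann             ``w(i) = (1 - cos(2*pi*i/I)) / 2``
bartlett_hann    ``w(i) = a0 - a1*|i/I - 1/2| - a2*cos(2*pi*i/I)``
                 with ``a0 = 0.62, a1 = 0.48, a2 = 0.38``
triangular       ``w(i) = 1 - |2*i/I - 1|``
===============  =====================================================

The pyramidal window (non-separable) weighs each pixel by its relative
distance to the patch border, ``W = alpha * D_e / (D_c + D_e)``, where
``D_e`` is the distance to the nearest border pixel, ``D_c`` the distance to
the patch centre, and ``alpha`` scales the weights to mean exactly 1.  It is
zero on the whole border ring and does *not* partition unity, so a
reconstruction using it must divide by the assembled weight field.

At the image borders no neighbouring patch exists to make up the tapered
weight, so border and corner patches receive dedicated variants whose
outward-facing half is flat (weight 1): per axis the profile is replaced by
1 on the outward half.  ``assemble_window_field`` tiles all variants over an
image and is the test surface for the partition-of-unity property.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .tiling import ROLE_TO_AXES, AxisRole, plan_grid, role_name

__all__ = [
    "WindowKind",
    "Window1D",
    "Window2D",
    "PyramidalParts",
    "SEPARABLE_KINDS",
    "TAPERING_KINDS",
    "BARTLETT_HANN_A0",
    "BARTLETT_HANN_A1",
    "BARTLETT_HANN_A2",
    "make_window_1d",
    "make_window_2d",
    "make_border_window",
    "make_corner_window",
    "window_for_role",
    "pyramidal_parts",
    "assemble_window_field",
]

#: Bartlett-Hann cosine/triangle mixture coefficients.
BARTLETT_HANN_A0 = 0.62
BARTLETT_HANN_A1 = 0.48
BARTLETT_HANN_A2 = 0.38


class WindowKind(str, enum.Enum):
    AVERAGE = "average"
    HANN = "hann"
    BARTLETT_HANN = "bartlett_hann"
    TRIANGULAR = "triangular"
    PYRAMIDAL = "pyramidal"


#: Kinds expressible as an outer product of 1-D profiles.
SEPARABLE_KINDS = (
    WindowKind.AVERAGE,
    WindowKind.HANN,
    WindowKind.BARTLETT_HANN,
    WindowKind.TRIANGULAR,
)

#: Kinds whose 1-D profile tapers to 0 at the patch border.
TAPERING_KINDS = (
    WindowKind.HANN,
    WindowKind.BARTLETT_HANN,
    WindowKind.TRIANGULAR,
)


@dataclass(frozen=True)
class Window1D:
    values: np.ndarray
    kind: WindowKind


@dataclass(frozen=True)
class Window2D:
    weights: np.ndarray  # (height, width), non-negative
    kind: WindowKind
    role: str  # "interior", "up", ..., "down_right", or "full"


@dataclass(frozen=True)
class PyramidalParts:
    """Distance grids and normaliser behind the pyramidal window."""

    edge_distance: np.ndarray    # D_e, zero exactly on the outer pixel ring
    center_distance: np.ndarray  # D_c, distance to the patch centre
    alpha: float                 # scales the weights to mean exactly 1


def _check_size(size: int, what: str = "window size") -> int:
    if size != int(size) or int(size) < 2 or int(size) % 2:
        raise ValueError(
            f"{what} must be an even integer >= 2 so that the half-stride "
            f"{what}/2 is integral; got {size!r}"
        )
    return int(size)


def make_window_1d(
    kind: WindowKind | str, size: int, *, strict_paper: bool = False
) -> Window1D:
    """Build the 1-D profile of a separable window.

    ``strict_paper`` switches to the as-printed textbook variants (symmetric
    Hann with denominator ``I - 1``; Bartlett-Hann with a ``+a1`` triangle
    term).  Those variants do not sum to 1 at half stride and exist only for
    comparison.
    """
    kind = WindowKind(kind)
    if kind is WindowKind.PYRAMIDAL:
        raise ValueError(
            "the pyramidal window cannot be described in separable form; "
            "build it with make_window_2d"
        )
    size = _check_size(size)
    i = np.arange(size, dtype=np.float64)
    if kind is WindowKind.AVERAGE:
        values = np.full(size, 0.5)
    elif kind is WindowKind.HANN:
        denom = size - 1 if strict_paper else size
        values = 0.5 * (1.0 - np.cos(2.0 * np.pi * i / denom))
    elif kind is WindowKind.BARTLETT_HANN:
        a1 = BARTLETT_HANN_A1 if strict_paper else -BARTLETT_HANN_A1
        values = (
            BARTLETT_HANN_A0
            + a1 * np.abs(i / size - 0.5)
            - BARTLETT_HANN_A2 * np.cos(2.0 * np.pi * i / size)
        )
    elif kind is WindowKind.TRIANGULAR:
        values = 1.0 - np.abs(2.0 * i / size - 1.0)
    return Window1D(values=values, kind=kind)


def pyramidal_parts(
    height: int,
    width: int,
    edge_metric: str = "chebyshev",
    center_metric: str = "euclidean",
) -> PyramidalParts:
    """Distance grids ``D_e``/``D_c`` and the mean-1 normaliser ``alpha``.

    ``D_e`` is the distance from each pixel to the nearest pixel of the
    patch's outer ring; because that ring is an axis-aligned rectangle, the
    Chebyshev, Euclidean and cityblock metrics all reduce to
    ``min(i, I-1-i, j, J-1-j)`` — the parameter is accepted for symmetry
    with ``center_metric``.  ``D_c`` is measured to the geometric patch
    centre at ``((J-1)/2, (I-1)/2)``.
    """
    height = _check_size(height, "window height")
    width = _check_size(width, "window width")
    if edge_metric not in ("chebyshev", "euclidean", "cityblock"):
        raise ValueError(f"unknown edge metric {edge_metric!r}")
    rows = np.arange(height, dtype=np.float64)[:, None]
    cols = np.arange(width, dtype=np.float64)[None, :]
    d_edge = np.minimum(
        np.minimum(rows, height - 1 - rows), np.minimum(cols, width - 1 - cols)
    )
    d_edge = np.broadcast_to(d_edge, (height, width)).copy()
    dr = np.abs(rows - (height - 1) / 2.0)
    dc = np.abs(cols - (width - 1) / 2.0)
    if center_metric == "euclidean":
        d_center = np.hypot(dr, dc)
    elif center_metric == "chebyshev":
        d_center = np.maximum(dr, dc)
    elif center_metric == "cityblock":
        d_center = dr + dc
    else:
        raise ValueError(f"unknown center metric {center_metric!r}")
    d_center = np.broadcast_to(d_center, (height, width)).copy()
    ratio = d_edge / (d_center + d_edge)
    alpha = float(height * width / ratio.sum())
    return PyramidalParts(edge_distance=d_edge, center_distance=d_center, alpha=alpha)


def make_window_2d(
    kind: WindowKind | str,
    height: int,
    width: int,
    *,
    strict_paper: bool = False,
    edge_metric: str = "chebyshev",
    center_metric: str = "euclidean",
) -> Window2D:
    """Interior 2-D window: separable outer product, or the pyramidal grid."""
    kind = WindowKind(kind)
    if kind is WindowKind.PYRAMIDAL:
        parts = pyramidal_parts(height, width, edge_metric, center_metric)
        weights = parts.alpha * (
            parts.edge_distance / (parts.center_distance + parts.edge_distance)
        )
        return Window2D(weights=weights, kind=kind, role="interior")
    wv = make_window_1d(kind, height, strict_paper=strict_paper).values
    wh = make_window_1d(kind, width, strict_paper=strict_paper).values
    return Window2D(weights=np.outer(wv, wh), kind=kind, role="interior")


def _axis_factor(
    kind: WindowKind, size: int, role: AxisRole, strict_paper: bool
) -> np.ndarray:
    if role is AxisRole.FULL:
        return np.ones(size, dtype=np.float64)
    w = make_window_1d(kind, size, strict_paper=strict_paper).values.copy()
    half = size // 2
    if role is AxisRole.LOW:
        w[:half] = 1.0  # outward (image-border) half is flat
    elif role is AxisRole.HIGH:
        w[half:] = 1.0
    return w


def window_for_role(
    kind: WindowKind | str,
    role: str | tuple[AxisRole, AxisRole],
    height: int,
    width: int,
    *,
    strict_paper: bool = False,
) -> Window2D:
    """Window variant for a patch role (interior, 4 edges, 4 corners, full).

    Per axis the 1-D profile is replaced by 1 on the half that faces an image
    border, compensating for the missing overlapping neighbour there, so that
    the tiled windows still sum to 1 everywhere.
    """
    if isinstance(role, str):
        try:
            axes = ROLE_TO_AXES[role]
        except KeyError:
            raise ValueError(f"unknown window role {role!r}") from None
    else:
        axes = (AxisRole(role[0]), AxisRole(role[1]))
    kind = WindowKind(kind)
    if kind is WindowKind.PYRAMIDAL:
        if axes != (AxisRole.INTERIOR, AxisRole.INTERIOR):
            raise ValueError(
                "border/corner variants are defined only for separable "
                "windows; the pyramidal window uses its interior form "
                "everywhere and a post-hoc renormalisation"
            )
        return make_window_2d(kind, height, width)
    vert, horz = axes
    wv = _axis_factor(kind, _check_size(height, "window height"), vert, strict_paper)
    wh = _axis_factor(kind, _check_size(width, "window width"), horz, strict_paper)
    return Window2D(weights=np.outer(wv, wh), kind=kind, role=role_name(vert, horz))


_BORDER_ROLES = ("up", "down", "left", "right")
_CORNER_ROLES = ("up_left", "up_right", "down_left", "down_right")


def make_border_window(
    kind: WindowKind | str,
    role: str,
    height: int,
    width: int,
    *,
    strict_paper: bool = False,
) -> Window2D:
    """Edge variant for a patch on one image border (flat outward half)."""
    if role not in _BORDER_ROLES:
        raise ValueError(f"border role must be one of {_BORDER_ROLES}; got {role!r}")
    if WindowKind(kind) is WindowKind.PYRAMIDAL:
        raise ValueError(
            "border windows are constructed from a 1-D profile; the "
            "pyramidal window has none"
        )
    return window_for_role(kind, role, height, width, strict_paper=strict_paper)


def make_corner_window(
    kind: WindowKind | str,
    role: str,
    height: int,
    width: int,
    *,
    strict_paper: bool = False,
) -> Window2D:
    """Corner variant: constant 1 on the outward quadrant, tapered elsewhere."""
    if role not in _CORNER_ROLES:
        raise ValueError(f"corner role must be one of {_CORNER_ROLES}; got {role!r}")
    if WindowKind(kind) is WindowKind.PYRAMIDAL:
        raise ValueError(
            "corner windows are constructed from a 1-D profile; the "
            "pyramidal window has none"
        )
    return window_for_role(kind, role, height, width, strict_paper=strict_paper)


def assemble_window_field(
    kind: WindowKind | str,
    image_height: int,
    image_width: int,
    patch: int,
    *,
    strict_paper: bool = False,
) -> np.ndarray:
    """Sum all role-appropriate windows tiled at half-patch stride.

    For separable kinds the result is the partition-of-unity test surface
    (it should be 1 everywhere).  For the pyramidal kind the interior window
    is tiled at every position — the resulting non-constant field is exactly
    the divisor its reconstruction needs.
    """
    kind = WindowKind(kind)
    grid = plan_grid(image_height, image_width, patch)
    field = np.zeros((image_height, image_width), dtype=np.float64)
    cache: dict[tuple[AxisRole, AxisRole], np.ndarray] = {}
    interior = (AxisRole.INTERIOR, AxisRole.INTERIOR)
    for (r, c), axes in zip(grid.origins, grid.axis_roles):
        key = interior if kind is WindowKind.PYRAMIDAL else axes
        if key not in cache:
            cache[key] = window_for_role(
                kind, key, patch, patch, strict_paper=strict_paper
            ).weights
        field[r : r + patch, c : c + patch] += cache[key]
    return field
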