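"""Half-stride patch tiling geometry.

Large images are processed as overlapping square patches laid out at a
stride of half a patch side.  For an image of ``n`` by ``m`` whole patches
this yields ``(2n - 1) * (2m - 1)`` patch positions instead of the ``n * m``
of a non-overlapping tiling: every interior pixel is covered by exactly
four patches, which is the geometric precondition for the window functions
in :mod:`winstitch.windows` to sum to one.

Patches are classified by which image borders they touch, per axis:
``interior`` (no border), ``low`` (top/left), ``high`` (bottom/right) or
``full`` (the patch spans the whole axis).  The reconstruction step picks
the matching edge/corner window variant from these tags.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "AxisRole",
    "PatchGrid",
    "CropRecord",
    "plan_grid",
    "pad_to_grid",
    "extract_patches",
    "role_name",
    "ROLE_TO_AXES",
]


class AxisRole(str, enum.Enum):
    """Position of a patch along one image axis."""

    INTERIOR = "interior"
    LOW = "low"       # touches the top (rows) or left (cols) image border
    HIGH = "high"     # touches the bottom (rows) or right (cols) image border
    FULL = "full"     # the patch spans the entire axis (single patch row/col)


_ROLE_NAMES: dict[tuple[AxisRole, AxisRole], str] = {
    (AxisRole.INTERIOR, AxisRole.INTERIOR): "interior",
    (AxisRole.LOW, AxisRole.INTERIOR): "up",
    (AxisRole.HIGH, AxisRole.INTERIOR): "down",
    (AxisRole.INTERIOR, AxisRole.LOW): "left",
    (AxisRole.INTERIOR, AxisRole.HIGH): "right",
    (AxisRole.LOW, AxisRole.LOW): "up_left",
    (AxisRole.LOW, AxisRole.HIGH): "up_right",
    (AxisRole.HIGH, AxisRole.LOW): "down_left",
    (AxisRole.HIGH, AxisRole.HIGH): "down_right",
    (AxisRole.FULL, AxisRole.FULL): "full",
}

#: Inverse mapping from role names to per-axis (vertical, horizontal) tags.
ROLE_TO_AXES: dict[str, tuple[AxisRole, AxisRole]] = {
    name: axes for axes, name in _ROLE_NAMES.items()
}


def role_name(vert: AxisRole, horz: AxisRole) -> str:
    """Human-readable name for a (vertical, horizontal) axis-role pair."""
    try:
        return _ROLE_NAMES[(vert, horz)]
    except KeyError:
        return f"{vert.value}|{horz.value}"


def _check_patch(patch: int) -> None:
    if patch != int(patch) or int(patch) < 2 or int(patch) % 2:
        raise ValueError(
            f"patch side must be an even integer >= 2 so that the half-patch "
            f"stride patch/2 is integral; got {patch!r}"
        )


def _axis_role(origin: int, first: int, last: int) -> AxisRole:
    low = origin == first
    high = origin == last
    if low and high:
        return AxisRole.FULL
    if low:
        return AxisRole.LOW
    if high:
        return AxisRole.HIGH
    return AxisRole.INTERIOR


@dataclass(frozen=True)
class PatchGrid:
    """Tiling geometry: image extent, patch size and ordered patch origins.

    Origins are (row, col) top-left corners, enumerated row-major at a
    stride of ``patch // 2``.  ``axis_roles[k]`` is the (vertical,
    horizontal) :class:`AxisRole` pair of ``origins[k]``.
    """

    image_height: int
    image_width: int
    patch: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    axis_roles: tuple[tuple[AxisRole, AxisRole], ...]

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    @property
    def roles(self) -> tuple[str, ...]:
        """Role name per origin (``interior``, ``up`` ... ``down_right``)."""
        return tuple(role_name(v, h) for v, h in self.axis_roles)

    def role_counts(self) -> Counter[str]:
        return Counter(self.roles)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_height": self.image_height,
                "image_width": self.image_width,
                "patch": self.patch,
                "stride": self.stride,
                "origins": [list(o) for o in self.origins],
                "roles": list(self.roles),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PatchGrid":
        d = json.loads(payload)
        return plan_grid(d["image_height"], d["image_width"], d["patch"])


def plan_grid(image_height: int, image_width: int, patch: int) -> PatchGrid:
    """Enumerate half-stride patch origins over an image.

    The image extent must be at least one patch and a multiple of the
    half-patch stride along each axis (use :func:`pad_to_grid` first
    otherwise).  For an extent of exactly ``n`` (resp. ``m``) patches this
    produces ``2n - 1`` origins per axis, ``(2n - 1) * (2m - 1)`` in total.
    """
    _check_patch(patch)
    stride = patch // 2
    for name, extent in (("height", image_height), ("width", image_width)):
        if extent < patch:
            raise ValueError(
                f"image {name} {extent} is smaller than the patch side {patch}; "
                f"pad the image first (pad_to_grid)"
            )
        if extent % stride:
            raise ValueError(
                f"image {name} {extent} is not a multiple of the half-patch "
                f"stride {stride}; pad the image first (pad_to_grid)"
            )
    rows = range(0, image_height - patch + 1, stride)
    cols = range(0, image_width - patch + 1, stride)
    last_r = image_height - patch
    last_c = image_width - patch
    origins = []
    axis_roles = []
    for r in rows:
        vr = _axis_role(r, 0, last_r)
        for c in cols:
            origins.append((r, c))
            axis_roles.append((vr, _axis_role(c, 0, last_c)))
    return PatchGrid(
        image_height=int(image_height),
        image_width=int(image_width),
        patch=int(patch),
        stride=stride,
        origins=tuple(origins),
        axis_roles=tuple(axis_roles),
    )


@dataclass(frozen=True)
class CropRecord:
    """Inverse of :func:`pad_to_grid`: remembers the original extent."""

    height: int
    width: int
    padded_height: int
    padded_width: int

    @property
    def is_identity(self) -> bool:
        return (self.height, self.width) == (self.padded_height, self.padded_width)

    def crop(self, array: np.ndarray) -> np.ndarray:
        if array.shape[:2] != (self.padded_height, self.padded_width):
            raise ValueError(
                f"array extent {array.shape[:2]} does not match the padded "
                f"extent {(self.padded_height, self.padded_width)}"
            )
        return array[: self.height, : self.width]


def _reflect_pad_axis(array: np.ndarray, axis: int, amount: int) -> np.ndarray:
    # np.pad(mode="symmetric") caps the pad width at the current extent, so
    # grow in passes when the target is more than double the input.
    while amount > 0:
        step = min(amount, array.shape[axis])
        pad = [(0, 0)] * array.ndim
        pad[axis] = (0, step)
        array = np.pad(array, pad, mode="symmetric")
        amount -= step
    return array


def pad_to_grid(image: np.ndarray, patch: int) -> tuple[np.ndarray, CropRecord]:
    """Reflect-pad an image (bottom/right) to the next multiple of ``patch``.

    Returns the padded array and a :class:`CropRecord` whose :meth:`~CropRecord.crop`
    restores the original extent bit-exactly after reconstruction.  Reflection
    is used so that no artificial intensity edge is introduced at the seam.
    """
    _check_patch(patch)
    image = np.asarray(image)
    if image.ndim < 2 or min(image.shape[:2]) < 2:
        raise ValueError(f"image must be at least 2x2; got shape {image.shape}")
    h, w = image.shape[:2]
    th = math.ceil(h / patch) * patch
    tw = math.ceil(w / patch) * patch
    padded = _reflect_pad_axis(image, 0, th - h)
    padded = _reflect_pad_axis(padded, 1, tw - w)
    return padded, CropRecord(height=h, width=w, padded_height=th, padded_width=tw)


def extract_patches(
    image: np.ndarray, grid: PatchGrid
) -> Iterator[tuple[tuple[int, int], np.ndarray]]:
    """Yield ``(origin, patch_view)`` pairs in the grid's row-major order."""
    image = np.asarray(image)
    if image.shape[:2] != (grid.image_height, grid.image_width):
        raise ValueError(
            f"image extent {image.shape[:2]} does not match the grid extent "
            f"{(grid.image_height, grid.image_width)}"
        )
    p = grid.patch
    for r, c in grid.origins:
        yield (r, c), image[r : r + p, c : c + p]
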