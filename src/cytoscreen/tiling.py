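"""Sliding-window decomposition of a slide into overlapping patches.

Coordinates are 0-based with origin at the top-left corner, x = column,
y = row. Patches are half-open rectangles [x, x+patch) x [y, y+patch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

Box = Tuple[float, float, float, float]  # (x0, y0, x1, y1)

DEFAULT_PATCH_SIZE = 1024
DEFAULT_STRIDE = 768  # 25% overlap so boundary-split cells appear whole in a neighbour


@dataclass(frozen=True)
class TileGrid:
    """Row-major grid of patch origins covering a slide."""

    width_px: int
    height_px: int
    patch_size_px: int
    stride_px: int
    origins: Tuple[Tuple[int, int], ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.origins)

    def __iter__(self):
        return iter(self.origins)


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    last = max(0, dim - patch)
    xs = list(range(0, last + 1, stride))
    if xs[-1] != last:
        xs.append(last)  # clamp final window so it abuts the edge
    return xs


def tile_slide(
    width_px: int,
    height_px: int,
    patch_size_px: int = DEFAULT_PATCH_SIZE,
    stride_px: int = DEFAULT_STRIDE,
) -> TileGrid:
    """Enumerate sliding-window patch origins covering the full image.

    Origins run 0, s, 2s, ... along each axis with the final origin
    clamped to max(0, dim - patch); every pixel is covered by at least
    one patch and no origin is duplicated.

    Raises
    ------
    ValueError
        If dimensions or patch size are < 1, or stride is outside
        [1, patch_size_px] (a stride larger than the patch leaves gaps).
    """
    if width_px < 1 or height_px < 1:
        raise ValueError("image dimensions must be >= 1")
    if patch_size_px < 1:
        raise ValueError("patch_size_px must be >= 1")
    if not (1 <= stride_px <= patch_size_px):
        raise ValueError(
            f"stride_px must satisfy 1 <= stride <= patch_size "
            f"(got stride={stride_px}, patch={patch_size_px})"
        )
    ys = _axis_origins(height_px, patch_size_px, stride_px)
    xs = _axis_origins(width_px, patch_size_px, stride_px)
    origins = tuple((x, y) for y in ys for x in xs)  # row-major
    return TileGrid(width_px, height_px, patch_size_px, stride_px, origins)


def to_slide_coords(box: Box, origin: Sequence[int]) -> Box:
    """Translate a patch-local box into slide coordinates."""
    ox, oy = origin
    x0, y0, x1, y1 = box
    return (x0 + ox, y0 + oy, x1 + ox, y1 + oy)


def tile_manifest_rows(slide_id: str, grid: TileGrid) -> Iterable[dict]:
    """Rows for a CSV tile manifest (slide_id, x, y, patch_size)."""
    for x, y in grid:
        yield {"slide_id": slide_id, "x": x, "y": y, "patch_size": grid.patch_size_px}
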