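"""Large field-of-view tile stitching.

Tiles acquired on an x-y translation stage with a small lateral overlap
(5% by default) are registered pairwise by phase correlation and composed
onto a common canvas, replacing an interactive pairwise-stitching step
with a reproducible implementation.

Conventions: a pairwise offset ``t = (dy, dx)`` means tile ``b`` samples
the scene ``t`` pixels further along than tile ``a`` (``b(r) = a(r + t)``
on the overlap), i.e. ``b``'s canvas position is ``a``'s position plus
``t``.  Offsets are integer pixels; the stage geometry makes subpixel
refinement marginal at 5% overlap.  Axial offsets are assumed zero and
one lateral layout is applied to all contrast channels of a bundle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .volumes import ScalarVolume

__all__ = ["TileSet", "MosaicLayout", "register_pair", "build_layout", "stitch"]


@dataclass
class TileSet:
    """Ordered tiles of one contrast plus the nominal acquisition grid."""

    tiles: Sequence[ScalarVolume]
    nominal_grid: tuple = (1, 1)
    overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.tiles = list(self.tiles)
        if not self.tiles:
            raise ValueError("TileSet needs at least one tile")
        shapes = {t.data.shape for t in self.tiles}
        if len(shapes) != 1:
            raise ValueError("all tiles must share the same shape")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1)")
        r, c = self.nominal_grid
        if r * c != len(self.tiles):
            raise ValueError("nominal_grid does not match the tile count")


@dataclass
class MosaicLayout:
    """Integer canvas offsets per tile plus pairwise confidences."""

    offsets: list
    confidences: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.offsets = [tuple(int(v) for v in o) for o in self.offsets]


def _enface(tile: ScalarVolume) -> np.ndarray:
    """Lateral (en-face) image used for registration: mean over depth."""
    data = tile.data
    if data.ndim == 2:
        return np.asarray(data, dtype=np.float64)
    if data.ndim == 3:
        return np.nanmean(data, axis=0)
    raise ValueError("tiles must be 2-D lateral images or (z, x, y) volumes")


def register_pair(a: np.ndarray, b: np.ndarray,
                  expected_offset: tuple = (0, 0),
                  search_margin: int | tuple | None = None,
                  eps: float = 1e-12) -> tuple[tuple, float]:
    """Phase-correlation registration of two equally shaped en-face images.

    The offset is the argmax of the phase-correlation surface restricted
    to ``expected_offset +/- search_margin`` (margin ``None`` searches the
    whole wrap-around range); confidence is the ratio of the peak to the
    second-highest value inside the search window.  A flat (zero
    variance) image yields ``(expected_offset, 0.0)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and equally shaped")
    ny, nx = a.shape
    ey, ex = (int(v) for v in expected_offset)
    if search_margin is None:
        my, mx = ny // 2, nx // 2
    elif np.isscalar(search_margin):
        my = mx = int(search_margin)
    else:
        my, mx = (int(v) for v in search_margin)

    if a.std() == 0 or b.std() == 0 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        return (ey, ex), 0.0

    Fa = np.fft.fft2(a - a.mean())
    Fb = np.fft.fft2(b - b.mean())
    cross = Fa * np.conj(Fb)
    surface = np.real(np.fft.ifft2(cross / (np.abs(cross) + eps)))

    dys = np.arange(ey - my, ey + my + 1)
    dxs = np.arange(ex - mx, ex + mx + 1)
    window = surface[np.mod(dys, ny)[:, None], np.mod(dxs, nx)[None, :]]
    flat = window.ravel()
    order = np.argsort(flat)
    peak = flat[order[-1]]
    second = flat[order[-2]] if flat.size > 1 else eps
    iy, ix = np.unravel_index(order[-1], window.shape)
    confidence = float(peak / max(second, eps)) if peak > 0 else 0.0
    return (int(dys[iy]), int(dxs[ix])), confidence


def build_layout(tileset: TileSet, search_margin: int | tuple | None = 15,
                 min_confidence: float = 0.0) -> MosaicLayout:
    """Chain pairwise registrations along the acquisition order.

    The expected step between consecutive tiles follows the nominal grid
    (row-major strip acquisition) at ``1 - overlap_fraction`` of the tile
    extent.  A registration whose confidence falls below
    ``min_confidence`` falls back to the expected (stage) offset.
    """
    tiles = tileset.tiles
    rows, cols = tileset.nominal_grid
    shape = _enface(tiles[0]).shape
    step_x = int(round(shape[1] * (1.0 - tileset.overlap_fraction)))
    step_y = int(round(shape[0] * (1.0 - tileset.overlap_fraction)))

    offsets = [(0, 0)]
    confidences = []
    for i in range(1, len(tiles)):
        r_prev, c_prev = divmod(i - 1, cols)
        r_cur, c_cur = divmod(i, cols)
        expected = ((r_cur - r_prev) * step_y, (c_cur - c_prev) * step_x)
        off, conf = register_pair(_enface(tiles[i - 1]), _enface(tiles[i]),
                                  expected_offset=expected,
                                  search_margin=search_margin)
        if conf < min_confidence:
            off = expected
        prev = offsets[-1]
        offsets.append((prev[0] + off[0], prev[1] + off[1]))
        confidences.append(conf)

    min_y = min(o[0] for o in offsets)
    min_x = min(o[1] for o in offsets)
    offsets = [(o[0] - min_y, o[1] - min_x) for o in offsets]
    return MosaicLayout(offsets=offsets, confidences=confidences)


def _feather_weight(shape: tuple) -> np.ndarray:
    """Linear ramp from the tile border inwards (minimum edge distance)."""
    wy = np.minimum(np.arange(shape[0]) + 1, np.arange(shape[0], 0, -1)).astype(np.float64)
    wx = np.minimum(np.arange(shape[1]) + 1, np.arange(shape[1], 0, -1)).astype(np.float64)
    return np.minimum.outer(wy, wx)


def _check_connected(boxes: list) -> None:
    n = len(boxes)
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        (y0, y1, x0, x1) = boxes[i]
        for j in range(n):
            if j in seen:
                continue
            (b0, b1, a0, a1) = boxes[j]
            if y0 <= b1 and b0 <= y1 and x0 <= a1 and a0 <= x1:
                seen.add(j)
                frontier.append(j)
    if len(seen) != n:
        raise ValueError("tile offsets produce a disconnected canvas")


def stitch(tiles: TileSet | Sequence[ScalarVolume], layout: MosaicLayout,
           blend: str = "feather") -> ScalarVolume:
    """Compose registered tiles onto one canvas.

    ``blend="feather"`` cross-fades overlaps with linear border-distance
    weights normalized to sum to one at every pixel; ``"overwrite"`` lets
    the later tile win.  Pixels covered by no tile are NaN.
    """
    if blend not in ("feather", "overwrite"):
        raise ValueError("blend must be 'feather' or 'overwrite'")
    tile_list = tiles.tiles if isinstance(tiles, TileSet) else list(tiles)
    if len(layout.offsets) != len(tile_list):
        raise ValueError("layout does not cover all tiles")

    first = tile_list[0]
    lat_shape = _enface(first).shape
    has_depth = first.data.ndim == 3
    boxes = [(oy, oy + lat_shape[0] - 1, ox, ox + lat_shape[1] - 1)
             for oy, ox in layout.offsets]
    _check_connected(boxes)
    min_y = min(b[0] for b in boxes)
    min_x = min(b[2] for b in boxes)
    H = max(b[1] for b in boxes) - min_y + 1
    W = max(b[3] for b in boxes) - min_x + 1

    depth = (first.data.shape[0],) if has_depth else ()
    if len(tile_list) == 1:  # identity; avoids weight-division round-off
        canvas = tile_list[0].data.copy()
    elif blend == "feather":
        num = np.zeros(depth + (H, W))
        den = np.zeros((H, W))
        w = _feather_weight(lat_shape)
        for tile, (oy, ox) in zip(tile_list, layout.offsets):
            ys = slice(oy - min_y, oy - min_y + lat_shape[0])
            xs = slice(ox - min_x, ox - min_x + lat_shape[1])
            num[..., ys, xs] += tile.data * w
            den[ys, xs] += w
        with np.errstate(invalid="ignore"):
            canvas = num / den
        canvas[..., den == 0] = np.nan
    else:
        canvas = np.full(depth + (H, W), np.nan)
        for tile, (oy, ox) in zip(tile_list, layout.offsets):
            ys = slice(oy - min_y, oy - min_y + lat_shape[0])
            xs = slice(ox - min_x, ox - min_x + lat_shape[1])
            canvas[..., ys, xs] = tile.data

    return ScalarVolume(canvas, units=first.units, name=first.name or "mosaic",
                        axial_pitch=first.axial_pitch,
                        lateral_pitch=first.lateral_pitch,
                        meta={"blend": blend, "offsets": list(layout.offsets)})
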