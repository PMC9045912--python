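"""Visualization products.

Pseudo-color composites follow the reliability-gating convention: a pixel
shows the birefringence hue only where the estimate is reliable, and a
gray shade of the scatter intensity otherwise; the intensity/DOPU
composite colors only pixels above an intensity floor so the background
stays gray.  Every composite records its colormap, value range and
threshold in a legend so the image can be reproduced bit-exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps

__all__ = ["CompositeImage", "pseudo_color_birefringence", "dopu_composite",
           "enface_projection"]

#: default display range of dB intensity images, relative to the volume max
DEFAULT_DB_RANGE = (-30.0, 0.0)


@dataclass
class CompositeImage:
    """RGB image plus the metadata needed to regenerate it."""

    rgb: np.ndarray               # (..., 3) floats in [0, 1]
    legend: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        if self.rgb.shape[-1] != 3:
            raise ValueError("rgb must have 3 channels")
        if np.nanmin(self.rgb) < 0 or np.nanmax(self.rgb) > 1:
            raise ValueError("rgb channels must lie in [0, 1]")


def _brightness(intensity_db: np.ndarray, db_range: tuple) -> np.ndarray:
    lo, hi = db_range
    with np.errstate(invalid="ignore"):
        b = (np.asarray(intensity_db, dtype=np.float64) - lo) / (hi - lo)
    return np.clip(np.nan_to_num(b, nan=0.0), 0.0, 1.0)


def _colorize(values: np.ndarray, value_range: tuple, cmap_name: str) -> np.ndarray:
    lo, hi = value_range
    with np.errstate(invalid="ignore"):
        t = (np.asarray(values, dtype=np.float64) - lo) / (hi - lo)
    t = np.clip(np.nan_to_num(t, nan=0.0), 0.0, 1.0)
    return colormaps[cmap_name](t)[..., :3]


def pseudo_color_birefringence(intensity_db, delta_n, reliability,
                               threshold: float = 0.7,
                               value_range: tuple = (0.0, 3.0e-3),
                               cmap: str = "turbo",
                               db_range: tuple = DEFAULT_DB_RANGE) -> CompositeImage:
    """Reliability-gated pseudo-color birefringence tomogram.

    Where ``reliability >= threshold`` the pixel hue encodes the
    birefringence over ``value_range`` and its brightness the clipped dB
    intensity; elsewhere the pixel is the gray intensity shade.
    """
    I = np.asarray(getattr(intensity_db, "data", intensity_db))
    dn = np.asarray(getattr(delta_n, "data", delta_n))
    rel = np.asarray(getattr(reliability, "data", reliability))
    if not (I.shape == dn.shape == rel.shape):
        raise ValueError("inputs must be aligned")
    b = _brightness(I, db_range)
    color = _colorize(dn, value_range, cmap)
    reliable = np.nan_to_num(rel, nan=0.0) >= threshold
    rgb = np.where(reliable[..., None], color * b[..., None],
                   np.repeat(b[..., None], 3, axis=-1))
    legend = {"contrast": "birefringence", "value_range": tuple(value_range),
              "colormap": cmap, "reliability_threshold": float(threshold),
              "db_range": tuple(db_range)}
    return CompositeImage(rgb=rgb, legend=legend)


def dopu_composite(intensity_db, dopu, intensity_floor: float = -25.0,
                   value_range: tuple = (0.0, 1.0), cmap: str = "viridis",
                   db_range: tuple = DEFAULT_DB_RANGE) -> CompositeImage:
    """Intensity/DOPU composite; background below the floor stays gray."""
    I = np.asarray(getattr(intensity_db, "data", intensity_db))
    d = np.asarray(getattr(dopu, "data", dopu))
    if I.shape != d.shape:
        raise ValueError("inputs must be aligned")
    b = _brightness(I, db_range)
    color = _colorize(d, value_range, cmap)
    foreground = np.nan_to_num(I, nan=-np.inf) >= intensity_floor
    rgb = np.where(foreground[..., None], color * b[..., None],
                   np.repeat(b[..., None], 3, axis=-1))
    legend = {"contrast": "dopu", "value_range": tuple(value_range),
              "colormap": cmap, "intensity_floor": float(intensity_floor),
              "db_range": tuple(db_range)}
    return CompositeImage(rgb=rgb, legend=legend)


def enface_projection(volume, z_range: tuple, mode: str = "mean") -> np.ndarray:
    """Depth-windowed en-face projection over ``[z0, z1)``.

    NaN (undefined) voxels are ignored; a lateral position with no
    defined voxel in the window is NaN.
    """
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float64)
    z0, z1 = (int(z) for z in z_range)
    if not 0 <= z0 < z1 <= data.shape[0]:
        raise ValueError("z_range must satisfy 0 <= z0 < z1 <= depth")
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    window = data[z0:z1]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(window, axis=0) if mode == "mean" else np.nanmax(window, axis=0)
    return out
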