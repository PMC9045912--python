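"""Core array containers shared across the package.

A :class:`JonesVolume` holds the raw polarization-sensitive measurement: a
2x2 complex Jones matrix per voxel describing the round-trip response of the
sample, together with the acquisition metadata (pixel pitches and the source
center wavelength) needed to convert phase to physical birefringence.

A :class:`ScalarVolume` holds one derived contrast (intensity, attenuation
coefficient, birefringence, DOPU, reliability) on the same grid.  Undefined
voxels (e.g. the unusable tail of the attenuation estimate) are NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: recognised unit tags for ScalarVolume
VALID_UNITS = ("linear", "dB", "mm^-1", "delta_n", "dopu", "reliability",
               "dimensionless")


@dataclass
class JonesVolume:
    """Volumetric Jones-matrix tomogram.

    Parameters
    ----------
    data : complex ndarray, shape ``(z, x[, y], 2, 2)``
        Measured round-trip Jones matrix per voxel.  Depth index 0 is the
        shallowest pixel; for 3-D volumes the last spatial axis indexes
        B-scans (slow scan direction).
    axial_pitch : float
        Depth pixel separation in micrometres.
    lateral_pitch : float
        Lateral pixel separation in micrometres.
    center_wavelength : float
        Source center wavelength in micrometres.
    meta : dict
        Free-form acquisition metadata (seed, system tag, ...).
    """

    data: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    center_wavelength: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.iscomplexobj(data):
            data = data.astype(np.complex128)
        if data.ndim < 3 or data.shape[-2:] != (2, 2):
            raise ValueError("JonesVolume data must have shape (z, ..., 2, 2)")
        if data.size == 0:
            raise ValueError("JonesVolume must not be empty")
        if not (np.all(np.isfinite(data.real)) and np.all(np.isfinite(data.imag))):
            raise ValueError("JonesVolume entries must be finite")
        for name in ("axial_pitch", "lateral_pitch", "center_wavelength"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number")
        self.data = data

    @property
    def n_depth(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        """Shape of the voxel grid, matrix axes dropped."""
        return self.data.shape[:-2]


@dataclass
class ScalarVolume:
    """One scalar contrast on a voxel grid.

    ``data`` may contain NaN where the contrast is undefined.  ``units`` is
    one of :data:`VALID_UNITS`; ``name`` records the generating contrast
    (provenance), e.g. ``"intensity"`` or ``"birefringence"``.
    """

    data: np.ndarray
    units: str
    name: str = ""
    axial_pitch: float = 1.0
    lateral_pitch: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.size == 0:
            raise ValueError("ScalarVolume must not be empty")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pitches must be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape
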