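"""Persistence of volumes, masks and specs.

Jones volumes are stored as an HDF5 group (complex dataset ``jones`` plus
pitch/wavelength attributes) with an optional JSON sidecar; scalar
volumes as 32-bit float TIFF stacks with a JSON sidecar carrying the
units, name and pitches; masks as 8-bit TIFF (0/255); phantom specs as
JSON or YAML.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .volumes import JonesVolume, ScalarVolume


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def save_jones_h5(path, vol: JonesVolume) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("jones", data=vol.data.astype(np.complex64))
        ds.attrs["axial_pitch_um"] = vol.axial_pitch
        ds.attrs["lateral_pitch_um"] = vol.lateral_pitch
        ds.attrs["center_wavelength_um"] = vol.center_wavelength
        fh.create_dataset("meta", data=json.dumps(vol.meta, default=str))


def load_jones_h5(path) -> JonesVolume:
    import h5py
    with h5py.File(path, "r") as fh:
        ds = fh["jones"]
        meta = json.loads(fh["meta"][()]) if "meta" in fh else {}
        return JonesVolume(ds[()].astype(np.complex128),
                           axial_pitch=float(ds.attrs["axial_pitch_um"]),
                           lateral_pitch=float(ds.attrs["lateral_pitch_um"]),
                           center_wavelength=float(ds.attrs["center_wavelength_um"]),
                           meta=meta)


def save_scalar_tiff(path, vol: ScalarVolume) -> None:
    import tifffile
    tifffile.imwrite(path, vol.data.astype(np.float32))
    with open(_sidecar(path), "w") as fh:
        json.dump({"units": vol.units, "name": vol.name,
                   "axial_pitch_um": vol.axial_pitch,
                   "lateral_pitch_um": vol.lateral_pitch,
                   "meta": vol.meta}, fh, indent=2, default=str)


def load_scalar_tiff(path) -> ScalarVolume:
    import tifffile
    data = tifffile.imread(path).astype(np.float64)
    side = _sidecar(path)
    info = {}
    if side.exists():
        with open(side) as fh:
            info = json.load(fh)
    return ScalarVolume(data, units=info.get("units", "linear"),
                        name=info.get("name", ""),
                        axial_pitch=info.get("axial_pitch_um", 1.0),
                        lateral_pitch=info.get("lateral_pitch_um", 1.0),
                        meta=info.get("meta", {}))


def save_mask_tiff(path, mask: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)),
                     photometric="minisblack")


def load_mask_tiff(path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path) > 0


def save_phantom_spec(path, spec) -> None:
    """PhantomSpec to JSON (default) or YAML by file extension."""
    from dataclasses import asdict
    payload = asdict(spec)
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        import yaml
        with open(p, "w") as fh:
            yaml.safe_dump(payload, fh)
    else:
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2)


def load_phantom_spec(path):
    from .synthetic import Layer, PhantomSpec
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        import yaml
        with open(p) as fh:
            payload = yaml.safe_load(fh)
    else:
        with open(p) as fh:
            payload = json.load(fh)
    payload["layers"] = [Layer(**l) for l in payload["layers"]]
    if isinstance(payload.get("lateral_size"), list):
        payload["lateral_size"] = tuple(payload["lateral_size"])
    return PhantomSpec(**payload)
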