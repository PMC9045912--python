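"""Synthetic phantoms with known ground truth.

This module is the forward model of the whole pipeline: it generates
Jones-matrix tomograms of layered tissue-like media (speckled exponential
backscatter, linear-retarder birefringence, polarization scrambling,
additive detector noise), raw spectral fringes for the SD-OCT
reconstruction chain, and two-region "tumor vs control" datasets with
per-B-scan masks, all with exact ground-truth maps.

Physical model
--------------
Each depth pixel of a layer acts as a linear retarder with single-pass
retardation ``eta = 2*pi*delta_n*axial_pitch/lambda0`` at orientation
``axis``.  The cumulative single-pass matrix ``J_cum(z)`` is the ordered
product of the per-pixel retarders, and the measured round-trip matrix is
the reciprocal form ``J_cum(z)^T @ J_cum(z)`` (so the round-trip
retardation per pixel is twice the single-pass value).  Fully developed
speckle multiplies each voxel by a circular complex Gaussian amplitude
whose mean power follows Beer-Lambert decay ``reflectivity *
exp(-2*mu*z)``.  Polarization scrambling with index ``s`` applies a random
SU(2) element per voxel, geodesically interpolated between the identity
(s=0) and a Haar-uniform rotation (s=1), so the s=1 limit produces
isotropically random polarization states on the Poincare sphere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .recon import SpectralFrameSet
from .volumes import JonesVolume


@dataclass
class Layer:
    """One homogeneous slab of a layered phantom.

    thickness : depth extent in pixels.
    mu : attenuation coefficient, mm^-1.
    delta_n : birefringence (refractive-index difference, dimensionless).
    axis : retarder orientation, rad.
    scrambling : polarization scrambling index in [0, 1].
    reflectivity : mean backscattered power at the layer top (linear).
    """

    thickness: int
    mu: float = 0.0
    delta_n: float = 0.0
    axis: float = 0.0
    scrambling: float = 0.0
    reflectivity: float = 1.0

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise ValueError("layer thickness must be >= 1 pixel")
        if self.mu < 0 or self.delta_n < 0 or self.reflectivity < 0:
            raise ValueError("mu, delta_n and reflectivity must be non-negative")
        if not 0.0 <= self.scrambling <= 1.0:
            raise ValueError("scrambling must lie in [0, 1]")


@dataclass
class PhantomSpec:
    """Full description of a layered phantom.

    Layers must tile ``[0, axial_size)`` exactly (their thicknesses sum to
    ``axial_size``).  ``lateral_size`` may be an int (B-scan) or a tuple
    ``(x, y)`` (volume).  ``snr_db=None`` means noiseless; otherwise
    additive complex white Gaussian noise is scaled so that the mean
    surface-voxel intensity exceeds the per-voxel noise intensity by
    ``snr_db`` decibels.  ``rolloff_db_per_mm`` optionally mimics the
    depth-dependent sensitivity roll-off of a spectrometer-based system.
    """

    layers: Sequence[Layer]
    lateral_size: object = 64
    axial_size: int = 128
    axial_pitch: float = 7.24       # um, JM-OCT depth pixel separation
    lateral_pitch: float = 12.0     # um
    center_wavelength: float = 1.31  # um
    snr_db: Optional[float] = None
    rolloff_db_per_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.layers = list(self.layers)
        if not self.layers:
            raise ValueError("at least one layer is required")
        if self.axial_size < 1:
            raise ValueError("axial_size must be >= 1")
        total = sum(l.thickness for l in self.layers)
        if total != self.axial_size:
            raise ValueError(
                f"layers must tile [0, axial_size): thicknesses sum to {total}, "
                f"axial_size is {self.axial_size}")
        if np.isscalar(self.lateral_size):
            if int(self.lateral_size) < 1:
                raise ValueError("lateral_size must be >= 1")
        elif any(int(s) < 1 for s in self.lateral_size):
            raise ValueError("lateral_size entries must be >= 1")
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0 or self.center_wavelength <= 0:
            raise ValueError("pitches and wavelength must be positive")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite (use None for noiseless)")

    @property
    def lateral_shape(self) -> tuple:
        if np.isscalar(self.lateral_size):
            return (int(self.lateral_size),)
        return tuple(int(s) for s in self.lateral_size)


@dataclass
class GroundTruth:
    """Per-voxel ground-truth maps aligned to a generated volume."""

    mu_map: np.ndarray            # mm^-1
    delta_n_map: np.ndarray       # dimensionless
    dopu_expected_map: np.ndarray  # noiseless large-kernel DOPU limit


def expected_dopu(scrambling) -> np.ndarray:
    """Ensemble (large-kernel, noiseless) DOPU of the scrambling model.

    For the slerp-mixed Haar rotation model the kernel-mean Stokes vector
    shrinks by ``kappa(s) = 1/3 + (2/3)*sinc(s) - (1/3)*(sinc(1+s) +
    sinc(1-s))`` (normalized sinc), with ``kappa(0)=1`` and ``kappa(1)=0``.
    """
    s = np.asarray(scrambling, dtype=np.float64)
    k = 1.0 / 3.0 + (2.0 / 3.0) * np.sinc(s) \
        - (1.0 / 3.0) * (np.sinc(1.0 + s) + np.sinc(1.0 - s))
    return np.clip(k, 0.0, 1.0)


def _linear_retarder(eta, theta) -> np.ndarray:
    """Jones matrix of a linear retarder, vectorized over leading axes."""
    eta = np.asarray(eta, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    c, s = np.cos(theta), np.sin(theta)
    ep = np.exp(0.5j * eta)
    em = np.conj(ep)
    J = np.empty(np.broadcast(eta, theta).shape + (2, 2), dtype=np.complex128)
    J[..., 0, 0] = c * c * ep + s * s * em
    J[..., 0, 1] = c * s * (ep - em)
    J[..., 1, 0] = J[..., 0, 1]
    J[..., 1, 1] = s * s * ep + c * c * em
    return J


def _per_depth_profiles(spec: PhantomSpec):
    nz = spec.axial_size
    mu = np.empty(nz)
    dn = np.empty(nz)
    ax = np.empty(nz)
    scr = np.empty(nz)
    refl = np.empty(nz)
    z0 = 0
    for layer in spec.layers:
        z1 = z0 + layer.thickness
        mu[z0:z1] = layer.mu
        dn[z0:z1] = layer.delta_n
        ax[z0:z1] = layer.axis
        scr[z0:z1] = layer.scrambling
        refl[z0:z1] = layer.reflectivity
        z0 = z1
    return mu, dn, ax, scr, refl


def _scramble_unitaries(rng: np.random.Generator, shape: tuple, s: np.ndarray) -> np.ndarray:
    """Random SU(2) per voxel: slerp(identity -> Haar rotation, weight s)."""
    q = rng.standard_normal(shape + (4,))
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    q[..., 0] = np.abs(q[..., 0])  # same rotation, short geodesic
    omega = np.arccos(np.clip(q[..., 0], -1.0, 1.0))
    sin_om = np.sin(omega)
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = np.where(sin_om[..., None] > 1e-12,
                        q[..., 1:] / np.where(sin_om[..., None] > 1e-12,
                                              sin_om[..., None], 1.0),
                        0.0)
    s_b = np.broadcast_to(np.reshape(s, (-1,) + (1,) * (len(shape) - 1)), shape)
    w = np.cos(s_b * omega)
    vec = np.sin(s_b * omega)[..., None] * nhat
    U = np.empty(shape + (2, 2), dtype=np.complex128)
    U[..., 0, 0] = w + 1j * vec[..., 0]
    U[..., 0, 1] = vec[..., 1] + 1j * vec[..., 2]
    U[..., 1, 0] = -vec[..., 1] + 1j * vec[..., 2]
    U[..., 1, 1] = w - 1j * vec[..., 0]
    return U


def generate_phantom(spec: PhantomSpec) -> tuple[JonesVolume, GroundTruth]:
    """Generate a speckled Jones-matrix volume and its ground truth.

    Identical specs (including the seed) produce bit-identical volumes.
    """
    nz = spec.axial_size
    lat = spec.lateral_shape
    shape = (nz,) + lat
    rng = np.random.default_rng(spec.seed)

    mu, dn, ax, scr, refl = _per_depth_profiles(spec)
    eta = 2.0 * np.pi * dn * spec.axial_pitch / spec.center_wavelength
    j_pix = _linear_retarder(eta, ax)                       # (nz, 2, 2)
    j_cum = np.empty_like(j_pix)
    j_cum[0] = j_pix[0]
    for z in range(1, nz):
        j_cum[z] = j_pix[z] @ j_cum[z - 1]
    j_sym = np.swapaxes(j_cum, -1, -2) @ j_cum              # reciprocal round trip

    dz_mm = spec.axial_pitch * 1e-3
    optical_depth = np.concatenate(([0.0], np.cumsum(mu[:-1]))) * dz_mm
    power = refl * np.exp(-2.0 * optical_depth)
    if spec.rolloff_db_per_mm:
        z_mm = np.arange(nz) * dz_mm
        power = power * 10.0 ** (-spec.rolloff_db_per_mm * z_mm / 10.0)

    depth_bc = (nz,) + (1,) * len(lat)
    g = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    amp = np.sqrt(power / 2.0).reshape(depth_bc) * g        # E|amp|^2 = power
    data = amp[..., None, None] * j_sym.reshape(depth_bc + (2, 2))

    if np.any(scr > 0):
        U = _scramble_unitaries(rng, shape, scr)
        data = U @ data

    if spec.snr_db is not None:
        # noise intensity per voxel = mean(|n_ij|^2) = sigma^2 per entry
        noise_power = power[0] / 10.0 ** (spec.snr_db / 10.0)
        sig = np.sqrt(noise_power / 2.0)
        data = data + sig * (rng.standard_normal(shape + (2, 2))
                             + 1j * rng.standard_normal(shape + (2, 2)))

    gt = GroundTruth(
        mu_map=np.broadcast_to(mu.reshape(depth_bc), shape).copy(),
        delta_n_map=np.broadcast_to(dn.reshape(depth_bc), shape).copy(),
        dopu_expected_map=np.broadcast_to(expected_dopu(scr).reshape(depth_bc), shape).copy(),
    )
    vol = JonesVolume(
        data,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        center_wavelength=spec.center_wavelength,
        meta={"seed": spec.seed, "snr_db": spec.snr_db},
    )
    return vol, gt


def generate_fringes(reflectors: Sequence[tuple], n_samples: int = 1024, *,
                     n_alines: int = 32, axial_pitch: float = 2.5,
                     center_wavelength: float = 0.84,
                     source_fwhm_frac: float = 0.5, dc_level: float = 1.0,
                     dispersion: tuple = (0.0, 0.0), k_warp: float = 0.0,
                     noise_std: float = 0.0, random_phase: bool = True,
                     seed: int = 0) -> SpectralFrameSet:
    """Simulate raw spectral fringes of point reflectors.

    Parameters
    ----------
    reflectors : sequence of (depth_um, amplitude)
        Single-pass depths in micrometres; each must lie inside the
        unambiguous range ``n_samples/2 * axial_pitch``.
    axial_pitch : target depth pixel pitch in micrometres; sets the sampled
        k span to ``pi / axial_pitch``.
    k_warp : in (-1, 1); 0 gives a linear k grid, otherwise a mild
        quadratic warp emulating an uncalibrated spectrometer axis.
    random_phase : randomize each reflector's fringe phase per A-line
        (fully developed speckle), so the average-spectrum subtraction of
        the reconstruction removes the DC term but not the signal.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    if not -1.0 < k_warp < 1.0:
        raise ValueError("k_warp must lie in (-1, 1)")
    z_max = n_samples / 2.0 * axial_pitch
    for depth, _ in reflectors:
        if not 0.0 < depth < z_max:
            raise ValueError(
                f"reflector depth {depth} um outside the unambiguous range (0, {z_max}) um")

    rng = np.random.default_rng(seed)
    span = np.pi / axial_pitch                  # rad/um
    k0 = 2.0 * np.pi / center_wavelength
    u = np.linspace(0.0, 1.0, n_samples)
    k = k0 - span / 2.0 + span * (u + k_warp * u * (1.0 - u))

    sigma = source_fwhm_frac * span / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    envelope = np.exp(-0.5 * ((k - k0) / sigma) ** 2)
    a2, a3 = dispersion
    phi_disp = a2 * (k - k0) ** 2 + a3 * (k - k0) ** 3

    spectra = np.empty((n_alines, n_samples))
    for line in range(n_alines):
        fringe = np.full(n_samples, dc_level)
        for depth, amplitude in reflectors:
            psi = rng.uniform(0.0, 2.0 * np.pi) if random_phase else 0.0
            fringe = fringe + amplitude * np.cos(2.0 * k * depth + phi_disp + psi)
        spectra[line] = envelope * fringe
    if noise_std > 0:
        spectra = spectra + noise_std * rng.standard_normal(spectra.shape)

    return SpectralFrameSet(spectra, k, dispersion=dispersion,
                            axial_pitch=axial_pitch, k0=k0,
                            meta={"seed": seed})


@dataclass
class RegionEffect:
    """Parameter shifts applied to the tumor region relative to control.

    Defaults reproduce the qualitative tumor signature used throughout the
    package: lowered birefringence, lowered scrambling (hence raised DOPU)
    and raised attenuation.  A zero-shift effect gives identical regions.
    """

    delta_n_shift: float = -1.0e-3
    scrambling_shift: float = -0.2
    mu_shift: float = 1.0


#: muscle-like control-region parameters of the two-region dataset
CONTROL_BASE = dict(mu=2.0, delta_n=1.8e-3, axis=0.5, scrambling=0.3,
                    reflectivity=1.0)


def generate_tumor_control_dataset(effect: RegionEffect | None = None,
                                   n_bscans: int = 32, *,
                                   bscan_shape: tuple = (128, 64),
                                   snr_db: float = 25.0,
                                   control: dict | None = None,
                                   seed: int = 0):
    """Generate a two-region volume with per-B-scan tumor/control masks.

    The volume is ``(z, x, bscan)``; the left lateral half is the
    muscle-like control region, the right half the tumor region with the
    requested parameter shifts.  Masks leave a lateral guard band around
    the region boundary (wider than the default DOPU kernel) and exclude
    the deepest quarter, where the attenuation estimate is tail-biased.

    Returns ``(JonesVolume, RegionMaskSet, GroundTruth)``.
    """
    from .stats import RegionMaskSet  # local import to avoid a cycle

    if effect is None:
        effect = RegionEffect()
    base = dict(CONTROL_BASE)
    if control:
        base.update(control)
    nz, nx = bscan_shape
    if nx < 16 or nz < 16:
        raise ValueError("bscan_shape too small for two guarded regions")
    half = nx // 2

    tumor = dict(base)
    tumor["delta_n"] = max(0.0, base["delta_n"] + effect.delta_n_shift)
    tumor["scrambling"] = float(np.clip(base["scrambling"] + effect.scrambling_shift, 0.0, 1.0))
    tumor["mu"] = max(0.0, base["mu"] + effect.mu_shift)

    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2 ** 31) for s in ss.generate_state(2)]
    volumes, truths = [], []
    for params, sub_seed in ((base, seeds[0]), (tumor, seeds[1])):
        spec = PhantomSpec(
            layers=[Layer(thickness=nz, **params)],
            lateral_size=(half, n_bscans), axial_size=nz,
            snr_db=snr_db, seed=sub_seed)
        vol, gt = generate_phantom(spec)
        volumes.append(vol)
        truths.append(gt)

    data = np.concatenate([volumes[0].data, volumes[1].data], axis=1)
    gt = GroundTruth(
        mu_map=np.concatenate([truths[0].mu_map, truths[1].mu_map], axis=1),
        delta_n_map=np.concatenate([truths[0].delta_n_map, truths[1].delta_n_map], axis=1),
        dopu_expected_map=np.concatenate(
            [truths[0].dopu_expected_map, truths[1].dopu_expected_map], axis=1),
    )
    jones = JonesVolume(data, axial_pitch=volumes[0].axial_pitch,
                        lateral_pitch=volumes[0].lateral_pitch,
                        center_wavelength=volumes[0].center_wavelength,
                        meta={"seed": seed, "effect": vars(effect)})

    z_lo, z_hi = 6, int(0.75 * nz)
    guard = 3
    control_mask = np.zeros((n_bscans, nz, 2 * half), dtype=bool)
    tumor_mask = np.zeros_like(control_mask)
    control_mask[:, z_lo:z_hi, 2:half - guard] = True
    tumor_mask[:, z_lo:z_hi, half + guard:2 * half - 2] = True
    masks = RegionMaskSet(masks={"control": control_mask, "tumor": tumor_mask},
                          volume_ref=f"tumor_control_seed{seed}")
    return jones, masks, gt
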