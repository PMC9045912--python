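"""Unit and property tests of the four JM-OCT contrasts."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jmoct import (JonesVolume, Layer, PhantomSpec, ScalarVolume,
                   attenuation_depth_resolved, dopu, generate_phantom,
                   local_birefringence, scatter_intensity)

PITCH = 7.24  # um
LAMBDA = 1.31  # um


def _jones(data, **kw):
    kw.setdefault("axial_pitch", PITCH)
    kw.setdefault("lateral_pitch", 12.0)
    kw.setdefault("center_wavelength", LAMBDA)
    return JonesVolume(np.asarray(data, dtype=np.complex128), **kw)


class TestScatterIntensity:
    def test_identity_matrix_gives_half(self):
        vol = _jones(np.eye(2).reshape(1, 1, 2, 2))
        assert scatter_intensity(vol).data[0, 0] == pytest.approx(0.5)

    def test_all_twos_gives_four(self):
        vol = _jones(np.full((1, 1, 2, 2), 2.0))
        assert scatter_intensity(vol).data[0, 0] == pytest.approx(4.0)

    def test_matches_per_voxel_bruteforce(self, rng):
        data = rng.standard_normal((8, 8, 8, 2, 2)) + 1j * rng.standard_normal((8, 8, 8, 2, 2))
        vol = _jones(data)
        got = scatter_intensity(vol).data
        for idx in np.ndindex(8, 8, 8):
            expect = sum(abs(data[idx][i, j]) ** 2 for i in range(2) for j in range(2)) / 4
            assert got[idx] == pytest.approx(expect, rel=1e-12)

    def test_invariant_to_per_voxel_unit_phase(self, rng):
        data = rng.standard_normal((4, 5, 2, 2)) + 1j * rng.standard_normal((4, 5, 2, 2))
        phase = np.exp(1j * rng.uniform(0, 2 * np.pi, (4, 5)))
        a = scatter_intensity(_jones(data)).data
        b = scatter_intensity(_jones(data * phase[..., None, None])).data
        assert np.allclose(a, b, rtol=1e-12)

    def test_db_mode_references_volume_max(self, rng):
        data = rng.standard_normal((4, 4, 2, 2)) + 0j
        db = scatter_intensity(_jones(data), db=True).data
        assert db.max() == pytest.approx(0.0, abs=1e-12)


class TestAttenuation:
    def test_geometric_series_closed_form(self):
        """Noiseless discrete exponential: the estimator converges to
        (exp(2*mu*Delta)-1)/(2*Delta) at every pixel with a long tail."""
        mu_t, delta = 1.0, PITCH * 1e-3
        I = np.exp(-2.0 * mu_t * delta) ** np.arange(4096.0)
        vol = ScalarVolume(I[:, None], units="linear", axial_pitch=PITCH)
        mu = attenuation_depth_resolved(vol).data[:2048, 0]
        expect = (np.exp(2 * mu_t * delta) - 1) / (2 * delta)
        assert np.max(np.abs(mu - expect)) < 1e-9
        # exact debiasing inverts the discretization bias
        mu_db = attenuation_depth_resolved(vol, debias=True).data[:2048, 0]
        assert np.max(np.abs(mu_db - mu_t)) < 1e-9

    def test_constant_intensity_forces_algebraic_form(self):
        n, delta = 32, PITCH * 1e-3
        vol = ScalarVolume(np.ones((n, 1)), units="linear", axial_pitch=PITCH)
        mu = attenuation_depth_resolved(vol).data[:, 0]
        i = np.arange(n - 1)
        assert np.allclose(mu[:-1], 1.0 / (2 * delta * (n - 1 - i)), rtol=1e-12)
        assert np.isnan(mu[-1])  # empty tail is masked, not infinite

    @settings(max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, scale):
        I = np.exp(-0.1 * np.arange(64.0))[:, None]
        a = attenuation_depth_resolved(ScalarVolume(I, units="linear", axial_pitch=PITCH)).data
        b = attenuation_depth_resolved(ScalarVolume(scale * I, units="linear", axial_pitch=PITCH)).data
        assert np.allclose(a[:-1], b[:-1], rtol=1e-9)

    def test_zero_tail_masked_not_infinite(self):
        I = np.zeros((16, 1))
        I[2, 0] = 1.0
        mu = attenuation_depth_resolved(
            ScalarVolume(I, units="linear", axial_pitch=PITCH)).data[:, 0]
        assert np.all(np.isnan(mu[2:]))  # nothing behind the lone reflector
        assert not np.any(np.isinf(mu))

    def test_rejects_nonlinear_units_and_negative_intensity(self):
        with pytest.raises(ValueError):
            attenuation_depth_resolved(
                ScalarVolume(np.ones((4, 1)), units="dB", axial_pitch=PITCH))
        with pytest.raises(ValueError):
            attenuation_depth_resolved(
                ScalarVolume(-np.ones((4, 1)), units="linear", axial_pitch=PITCH))


def _retarder_phantom(delta_rt_per_sep, depth_sep, nz=40, lateral=6, seed=0,
                      snr_db=None):
    """Phantom whose round-trip retardation per depth_sep is prescribed."""
    dn = delta_rt_per_sep * LAMBDA / (4 * np.pi * depth_sep * PITCH)
    spec = PhantomSpec(layers=[Layer(thickness=nz, delta_n=dn, axis=0.7)],
                       lateral_size=lateral, axial_size=nz, axial_pitch=PITCH,
                       center_wavelength=LAMBDA, snr_db=snr_db, seed=seed)
    return generate_phantom(spec), dn


class TestLocalBirefringence:
    def test_identity_medium_gives_zero(self, identity_phantom):
        vol, _ = identity_phantom
        dn, rel = local_birefringence(vol, depth_sep=2)
        assert np.nanmax(np.abs(dn.data)) < 1e-12
        assert np.all(rel.data[:-2] == 1.0)

    @pytest.mark.parametrize("delta_rt", [0.05, 0.2, 1.0])
    def test_homogeneous_retarder_exact(self, delta_rt):
        (vol, _), dn_true = _retarder_phantom(delta_rt, depth_sep=2)
        dn, _ = local_birefringence(vol, depth_sep=2)
        assert np.nanmax(np.abs(dn.data - dn_true)) < 1e-9

    def test_retardation_wrapped_and_nonnegative(self, rng):
        data = rng.standard_normal((16, 16, 2, 2)) + 1j * rng.standard_normal((16, 16, 2, 2))
        dn, rel = local_birefringence(_jones(data), depth_sep=1)
        finite = dn.data[np.isfinite(dn.data)]
        max_dn = np.pi * LAMBDA / (4 * np.pi * 1 * PITCH)
        assert np.all(finite >= 0) and np.all(finite <= max_dn + 1e-12)
        assert np.all((rel.data >= 0) & (rel.data <= 1))

    def test_map_estimator_reduces_zero_retardation_bias(self):
        """At 20 dB SNR and true delta=0 the naive eigen-phase estimate is
        positively biased; the MAP posterior mode must lower the mean."""
        nz, lateral = 34, 64  # ~2000 estimated pixels
        spec = PhantomSpec(layers=[Layer(thickness=nz, delta_n=0.0)],
                           lateral_size=lateral, axial_size=nz,
                           snr_db=20.0, seed=7)
        vol, _ = generate_phantom(spec)
        noise_power = 1.0 / 10 ** 2.0  # surface power 1, 20 dB
        dn_naive, _ = local_birefringence(vol, estimator="naive",
                                          noise_power=noise_power)
        dn_map, rel = local_birefringence(vol, estimator="map",
                                          noise_power=noise_power)
        assert np.nanmean(dn_map.data) < np.nanmean(dn_naive.data)
        assert np.all((rel.data >= 0) & (rel.data <= 1))

    def test_map_requires_noise_model(self, identity_phantom):
        vol, _ = identity_phantom
        with pytest.raises(ValueError, match="noise_power"):
            local_birefringence(vol, estimator="map")

    def test_singular_pixels_marked_unreliable(self):
        data = np.tile(np.eye(2, dtype=complex), (6, 3, 1, 1))
        data[2, 1] = 0.0  # dead voxel
        dn, rel = local_birefringence(_jones(data), depth_sep=1)
        assert np.isnan(dn.data[2, 1]) and rel.data[2, 1] == 0.0
        assert np.isfinite(dn.data[2, 0])

    def test_depth_sep_validation(self, identity_phantom):
        vol, _ = identity_phantom
        with pytest.raises(ValueError):
            local_birefringence(vol, depth_sep=0)
        with pytest.raises(ValueError):
            local_birefringence(vol, depth_sep=vol.n_depth)


class TestDopu:
    def test_uniform_state_gives_one(self, identity_phantom):
        vol, _ = identity_phantom
        d = dopu(vol, kernel=(3, 5)).data
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_equal_orthogonal_mixture_gives_zero(self):
        # voxels alternate between H- and V-transmitting matrices; the
        # fifth voxel is dead and excluded, leaving 2+2 orthogonal states
        swap = np.array([[0, 1], [1, 0]], dtype=complex)
        row = [np.eye(2), swap, np.eye(2), swap, np.zeros((2, 2))]
        data = np.stack(row).reshape(1, 5, 2, 2)
        d = dopu(_jones(data), kernel=(1, 5)).data
        assert d[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_global_unitary(self, rng):
        data = rng.standard_normal((8, 9, 2, 2)) + 1j * rng.standard_normal((8, 9, 2, 2))
        theta = 0.83
        U = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]]) @ np.diag([np.exp(0.3j), np.exp(-0.3j)])
        a = dopu(_jones(data), kernel=(3, 3)).data
        b = dopu(_jones(U @ data), kernel=(3, 3)).data
        assert np.allclose(a, b, atol=1e-10)

    def test_bounded_in_unit_interval(self, rng):
        data = rng.standard_normal((10, 10, 2, 2)) + 1j * rng.standard_normal((10, 10, 2, 2))
        d = dopu(_jones(data), kernel=(3, 3)).data
        finite = d[np.isfinite(d)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_isotropic_states_match_sphere_sampling_oracle(self, scrambled_phantom):
        """Kernel-mean DOPU of fully scrambled speckle must match the mean
        resultant length of kz*kx uniform unit vectors."""
        vol, _ = scrambled_phantom
        d = dopu(vol, kernel=(3, 5)).data[1:-1, 2:-2]  # interior kernels only
        rng = np.random.default_rng(0)
        v = rng.standard_normal((20000, 15, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        oracle = np.linalg.norm(v.mean(axis=1), axis=-1).mean()
        assert d.size >= 10_000
        assert abs(d.mean() - oracle) / oracle < 0.02

    def test_kernel_validation(self, identity_phantom):
        vol, _ = identity_phantom
        with pytest.raises(ValueError):
            dopu(vol, kernel=(2, 3))
        with pytest.raises(ValueError):
            dopu(vol, kernel=(3, 999))
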