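import numpy as np
import pytest
from scipy.optimize import minimize

from fosters import phantom, recon, sampling
from fosters.config import ReconConfig


def random_setup(rng, ny=12, nx=10, nt=5, ne=2, nc=3):
    maps = phantom.make_coil_maps(ny, nx, nc, seed=0)
    mask = sampling.generate_kt_mask(ny, nx, nt, 2, 0.1, seed=0).mask.astype(float)
    x = rng.standard_normal((ny, nx, nt, ne)) + 1j * rng.standard_normal(
        (ny, nx, nt, ne))
    y = rng.standard_normal((nc, ny, nx, nt, ne)) + 1j * rng.standard_normal(
        (nc, ny, nx, nt, ne))
    return maps, mask, x, y


class TestEncoding:
    def test_adjoint_identity_on_random_instances(self, rng):
        for _ in range(50):
            maps, mask, x, y = random_setup(rng)
            lhs = np.vdot(y, recon.encode(x, maps, mask))
            rhs = np.vdot(recon.encode_adjoint(y, maps, mask), x)
            assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_single_uniform_coil_full_mask_is_unitary_fft(self, rng):
        from fosters.fourier import fft2c

        x = rng.standard_normal((8, 8, 3, 1)) + 1j * rng.standard_normal((8, 8, 3, 1))
        maps = np.ones((1, 8, 8), dtype=complex)
        mask = np.ones((8, 8, 3))
        k = recon.encode(x, maps, mask)
        np.testing.assert_allclose(k[0], fft2c(x), atol=1e-12)
        back = recon.encode_adjoint(k, maps, mask)
        assert np.abs(back - x).max() < 1e-10

    def test_zero_image_gives_zero_samples(self):
        maps = np.ones((1, 6, 6), dtype=complex)
        mask = np.ones((6, 6, 2))
        assert np.all(recon.encode(np.zeros((6, 6, 2, 1), complex), maps, mask) == 0)

    def test_shape_mismatch_rejected(self, rng):
        maps, mask, x, _ = random_setup(rng)
        with pytest.raises(ValueError):
            recon.encode(x[:-1], maps, mask)


class TestSvt:
    def test_tau_zero_returns_input_unchanged(self, rng):
        m = rng.standard_normal((6, 4)) + 1j * rng.standard_normal((6, 4))
        assert recon.svt(m, 0.0) is m

    def test_diagonal_matrix_closed_form(self):
        out = recon.svt(np.diag([3.0, 1.0]).astype(complex), 2.0)
        np.testing.assert_allclose(np.abs(out), np.diag([1.0, 0.0]), atol=1e-12)

    def test_full_shrinkage_gives_zero(self, rng):
        m = rng.standard_normal((5, 3))
        tau = np.linalg.svd(m, compute_uv=False)[0] + 0.1
        assert np.abs(recon.svt(m.astype(complex), tau)).max() < 1e-12

    def test_matches_bruteforce_eigendecomposition(self, rng):
        # independent oracle: singular system from the eigen-decomposition
        # of A^H A, explicit shrinkage
        for _ in range(100):
            a = rng.standard_normal((20, 12)) + 1j * rng.standard_normal((20, 12))
            tau = rng.uniform(0, 3)
            w, v = np.linalg.eigh(a.conj().T @ a)
            s = np.sqrt(np.maximum(w[::-1], 0))
            v = v[:, ::-1]
            u = (a @ v) / s
            expected = (u * np.maximum(s - tau, 0)) @ v.conj().T
            np.testing.assert_allclose(recon.svt(a, tau), expected, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            recon.svt(np.array([[np.nan, 0], [0, 1.0]]), 0.5)


class TestTvProx:
    def test_constant_image_fixed_point(self):
        frame = np.full((6, 6), 2.7)
        assert np.abs(recon.tv_anisotropic(frame)).max() == 0
        np.testing.assert_allclose(recon.prox_tv(frame, 0.3), frame, atol=1e-10)

    def test_weight_zero_is_identity(self, rng):
        frame = rng.standard_normal((5, 5))
        assert recon.prox_tv(frame, 0.0) is frame

    def test_two_pixel_closed_form(self):
        # jump shrinks by 2w: prox([0, 1], w=1/4) = [1/4, 3/4]
        out = recon.prox_tv(np.array([[0.0, 1.0]]), 0.25, n_iter=50)
        np.testing.assert_allclose(out, [[0.25, 0.75]], atol=1e-8)

    def test_matches_direct_minimization_on_small_image(self, rng):
        x = rng.standard_normal((4, 4))
        w = 0.15

        def objective(z):
            z = z.reshape(4, 4)
            g = recon.tv_anisotropic(z)
            return 0.5 * np.sum((z - x) ** 2) + w * np.abs(g).sum()

        direct = minimize(objective, x.ravel(), method="Nelder-Mead",
                          options={"maxiter": 20000, "xatol": 1e-8,
                                   "fatol": 1e-10}).x.reshape(4, 4)
        ours = recon.prox_tv(x, w, n_iter=400)
        assert objective(ours.ravel()) <= objective(direct.ravel()) + 1e-6


class TestWavelet:
    def test_roundtrip_is_identity(self, rng):
        x = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        coeffs = recon.wavelet_transform(x)
        back = recon.wavelet_inverse(coeffs)
        assert np.abs(back - x).max() < 1e-10


@pytest.fixture(scope="module")
def small_kt_single_coil():
    from conftest import small_config

    cfg = small_config()
    truth = phantom.render_truth(cfg)
    echoes = phantom.simulate_dual_echo(truth, cfg.acquisition)
    pattern = sampling.generate_kt_mask(48, 48, cfg.n_frames, R=1, seed=0)
    maps = np.ones((1, 48, 48), dtype=complex)
    kt = phantom.acquire_kt(echoes, maps, pattern, snr=1e14,
                            acq=cfg.acquisition, seed=0)
    return echoes, kt


class TestSolvers:
    def test_unregularized_full_sampling_equals_inverse_fft(
            self, small_kt_single_coil):
        echoes, kt = small_kt_single_coil
        cfg = ReconConfig(alpha=0, beta=0, n_iter=3, dtype="complex128")
        out = recon.solve_lrs(kt, cfg)
        rel = np.abs(out.data - echoes.data).max() / np.abs(echoes.data).max()
        assert rel < 1e-6

    def test_wavelet_cs_unregularized_limit(self, small_kt_single_coil):
        echoes, kt = small_kt_single_coil
        cfg = ReconConfig(lam=0, n_iter=3, dtype="complex128")
        out = recon.solve_wavelet_cs(kt, cfg)
        rel = np.abs(out.data - echoes.data).max() / np.abs(echoes.data).max()
        assert rel < 1e-6

    def test_objective_monotone_and_recorded(self, small_kt):
        truth, kt = small_kt
        out = recon.solve_lrs(kt, ReconConfig(n_iter=8))
        assert len(out.objective_log) == 8
        assert np.all(np.diff(out.objective_log) <= 1e-3)

    def test_undersampled_recon_beats_zero_filled(self, small_kt, small_cfg):
        truth, kt = small_kt
        composite = np.abs(
            phantom.simulate_dual_echo(truth, small_cfg.acquisition).data)

        def nrmse(est):
            return np.sqrt(np.mean((np.abs(est) - composite) ** 2)) / composite.max()

        zf = recon.zero_filled(kt)
        out = recon.solve_lrs(kt, ReconConfig(n_iter=25))
        assert nrmse(out.data) < nrmse(zf.data)

    def test_large_alpha_drives_temporal_rank_one(self, small_kt):
        truth, kt = small_kt
        out = recon.solve_lrs(kt, ReconConfig(alpha=30.0, beta=0.0, n_iter=25))
        cas = out.data[..., 0].reshape(-1, out.data.shape[2])
        s = np.linalg.svd(cas, compute_uv=False)
        assert s[0] > 0
        assert (s[1:] / s[0] < 1e-6).all()

    def test_reconstruction_deterministic(self, small_kt):
        truth, kt = small_kt
        a = recon.solve_lrs(kt, ReconConfig(n_iter=4))
        b = recon.solve_lrs(kt, ReconConfig(n_iter=4))
        np.testing.assert_array_equal(a.data, b.data)
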