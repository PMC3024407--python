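"""k-t BLAST reconstruction: alias geometry, filter oracle, smoothing behavior.

The brute-force oracle used here rebuilds the whole chain with explicit DFT
matrices and per-alias-set 1xR linear systems, independent of the FFT-based
vectorized implementation.
"""

import numpy as np
import pytest

from ktblast_tpm.ktblast import (
    KTBlastReconstructor,
    SignalVarianceMap,
    alias_kernel,
    estimate_noise_psi,
    estimate_signal_variance,
    reconstruct_full,
    reconstruct_ktblast,
)
from ktblast_tpm.phantom import MotionModel, build_phantom, encode_velocity
from ktblast_tpm.sampling import (
    KSpaceSeries,
    acquire_training,
    image_to_kspace,
    kspace_to_image,
    make_kt_pattern,
    to_kspace,
    undersample,
)


# ---------------------------------------------------------------------------
# explicit-matrix transform helpers (oracle path, no FFTs)
# ---------------------------------------------------------------------------

def _centered_dft(n: int) -> np.ndarray:
    """Matrix of the centred unitary DFT used by the package k-space helpers."""
    c = n // 2
    idx = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(idx - c, idx - c) / n) / np.sqrt(n)


def _temporal_dft(n: int) -> np.ndarray:
    idx = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)


def _oracle_aliased_xf(kdata_yt: np.ndarray) -> np.ndarray:
    """Zero-filled k-(pe)-t data (n_pe, T) -> aliased x-f via explicit matrices."""
    n_pe, T = kdata_yt.shape
    Fy = _centered_dft(n_pe)
    Ft = _temporal_dft(T)
    img_yt = Fy.conj().T @ kdata_yt  # inverse spatial
    return img_yt @ Ft.T  # forward temporal per y


def _oracle_psf(mask: np.ndarray):
    """Brute-force PSF of the sampling mask: alias shifts and weights."""
    T, n_pe = mask.shape
    # delta in x-f at (0, 0) -> time series -> k lines -> mask -> aliased x-f
    xf = np.zeros((n_pe, T), complex)
    xf[0, 0] = 1.0
    Ft = _temporal_dft(T)
    Fy = _centered_dft(n_pe)
    img_yt = xf @ Ft.conj().T  # inverse temporal
    k_yt = Fy @ img_yt
    k_yt = k_yt * mask.T
    aliased = _oracle_aliased_xf(k_yt)
    nz = np.argwhere(np.abs(aliased) > 1e-9)
    return nz, aliased[nz[:, 0], nz[:, 1]]


def _oracle_reconstruct(kdata, mask, theta2, psi, baseline=True):
    """Per-alias-set regularized least-squares solve with explicit matrices.

    kdata: (E, T, n_ro, n_pe) zero-filled; theta2: (n_ro, n_pe, T).
    """
    E, T, n_ro, n_pe = kdata.shape
    shifts, weights = _oracle_psf(mask)
    R = len(weights)
    Fro = _centered_dft(n_ro)
    Ft = _temporal_dft(T)
    out = np.zeros_like(kdata)
    for e in range(E):
        d = kdata[e].copy()  # (T, n_ro, n_pe)
        if baseline:
            counts = mask.sum(axis=0)
            base_k = (d * mask[:, None, :]).sum(axis=0) / counts[None, :]
            d = d - base_k[None] * mask[:, None, :]
        # to hybrid (x, k_pe, t): invert readout only
        hyb = np.einsum("xu,tuy->txy", Fro.conj().T, d)
        est_imgs = np.zeros((T, n_ro, n_pe), complex)
        for x in range(n_ro):
            axf = _oracle_aliased_xf(hyb[:, x, :].T)  # (n_pe, T)
            est = np.zeros((n_pe, T), complex)
            dy = n_pe // R
            for y0 in range(dy):
                for f0 in range(T):
                    members = [((y0 - s[0]) % n_pe, (f0 - s[1]) % T) for s in shifts]
                    A = np.array([weights])  # 1 x R
                    Th = np.diag([theta2[x, m[0], m[1]] for m in members])
                    G = A @ Th @ A.conj().T + psi * np.eye(1)
                    sol = Th @ A.conj().T @ np.linalg.solve(G, np.array([[axf[y0, f0]]]))
                    for q, m in enumerate(members):
                        est[m[0], m[1]] = sol[q, 0]
            est_imgs[:, x, :] = (est @ Ft.conj().T).T  # inverse temporal
        if baseline:
            # baseline k-space (n_ro, n_pe) -> image via centred inverse on both axes
            base_img = Fro.conj().T @ base_k @ _centered_dft(n_pe).conj()
            est_imgs = est_imgs + base_img[None]
        out[e] = est_imgs
    return out


def _lattice_series(rng, n_pe=8, T=4, n_ro=2, E=1):
    imgs = rng.standard_normal((E, T, n_ro, n_pe)) + 1j * rng.standard_normal((E, T, n_ro, n_pe))
    return imgs, KSpaceSeries(image_to_kspace(imgs), np.ones((T, n_pe), bool))


class TestFullRecon:
    def test_round_trip_identity(self, rng):
        imgs, k = _lattice_series(rng)
        assert np.max(np.abs(reconstruct_full(k) - imgs)) < 1e-12

    def test_linearity(self, rng):
        _, k1 = _lattice_series(rng)
        _, k2 = _lattice_series(rng)
        a = 2.5 - 1.0j
        lhs = reconstruct_full(KSpaceSeries(a * k1.data + k2.data, k1.sampled))
        rhs = a * reconstruct_full(k1) + reconstruct_full(k2)
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_missing_lines_rejected(self, rng):
        _, k = _lattice_series(rng)
        ku = undersample(k, make_kt_pattern(8, 4, 2))
        with pytest.raises(ValueError):
            reconstruct_full(ku)


class TestAliasKernel:
    @pytest.mark.parametrize("n_pe, T, R", [(8, 4, 2), (12, 6, 3), (16, 8, 4), (12, 4, 4)])
    def test_kernel_matches_brute_force_dft_of_mask(self, n_pe, T, R):
        pat = make_kt_pattern(n_pe, T, R)
        shifts, weights = alias_kernel(pat)
        o_shifts, o_weights = _oracle_psf(pat.mask())
        order = np.lexsort((o_shifts[:, 1], o_shifts[:, 0]))
        np.testing.assert_array_equal(shifts, o_shifts[order])
        np.testing.assert_allclose(weights, o_weights[order], atol=1e-12)

    def test_kernel_has_R_members_on_lattice_shifts(self):
        shifts, weights = alias_kernel(make_kt_pattern(12, 6, 3))
        assert len(weights) == 3
        assert {tuple(s) for s in shifts} == {(0, 0), (4, 2), (8, 4)}
        np.testing.assert_allclose(np.abs(weights), 1 / 3, atol=1e-12)

    def test_indivisible_pe_grid_rejected(self):
        with pytest.raises(ValueError):
            alias_kernel(make_kt_pattern(10, 4, 4))


class TestSignalVariance:
    def test_static_scene_concentrates_at_dc_frequency(self, rng):
        img = rng.standard_normal((1, 1, 8, 8)) + 0j
        imgs = np.repeat(img, 6, axis=1)
        k = KSpaceSeries(image_to_kspace(imgs), np.ones((6, 8), bool))
        tr = acquire_training(k, 8)
        svm = estimate_signal_variance(tr, psi=1e-6)
        assert svm.theta2[..., 0].sum() > 0
        assert np.max(svm.theta2[..., 1:]) < 1e-20

    def test_zero_training_gives_zero_prior(self):
        k = KSpaceSeries(np.zeros((1, 4, 8, 8), complex), np.ones((4, 8), bool))
        svm = estimate_signal_variance(acquire_training(k, 8), psi=1.0)
        assert np.all(svm.theta2 == 0)

    def test_single_harmonic_peaks_at_its_frequency(self):
        T, n = 8, 16
        t = np.arange(T)
        imgs = np.zeros((1, T, n, n), complex)
        imgs[0, :, 8, 8] = np.exp(2j * np.pi * 3 * t / T)  # bright pixel oscillating at f = 3
        k = KSpaceSeries(image_to_kspace(imgs), np.ones((T, n), bool))
        svm = estimate_signal_variance(acquire_training(k, n), psi=1.0)
        profile = svm.theta2.sum(axis=(0, 1))
        assert np.argmax(profile) == 3

    def test_nonpositive_psi_rejected(self, rng):
        _, k = _lattice_series(rng)
        with pytest.raises(ValueError):
            estimate_signal_variance(acquire_training(k, 8), psi=0.0)


class TestKTBlastFilter:
    def test_R1_equals_direct_recon(self, rng):
        imgs, k = _lattice_series(rng)
        svm = SignalVarianceMap(np.ones((2, 8, 4)), psi=0.5)
        out = reconstruct_ktblast(k, make_kt_pattern(8, 4, 1), svm)
        rel = np.max(np.abs(out - imgs)) / np.max(np.abs(imgs))
        assert rel < 1e-10

    def test_exact_recovery_when_one_alias_member_active(self, rng):
        """psi -> 0 with a single non-zero theta2 per alias set: exact unaliasing."""
        n_pe, T, R, n_ro = 8, 4, 2, 2
        pat = make_kt_pattern(n_pe, T, R)
        # ground truth x-f supported only where theta2 is non-zero: pick the
        # y < n_pe/2 half, which never collides with its own alias partner
        xf = np.zeros((1, n_ro, n_pe, T), complex)
        xf[..., : n_pe // 2, :] = rng.standard_normal((1, n_ro, n_pe // 2, T))
        theta2 = np.zeros((n_ro, n_pe, T))
        theta2[:, : n_pe // 2, :] = 1.0
        from ktblast_tpm.ktblast import _from_xf

        imgs = _from_xf(xf)
        k = KSpaceSeries(image_to_kspace(imgs), np.ones((T, n_pe), bool))
        ku = undersample(k, pat)
        svm = SignalVarianceMap(theta2, psi=1e-14)
        out = reconstruct_ktblast(ku, pat, svm, baseline_correction=False)
        assert np.max(np.abs(out - imgs)) < 1e-6

    @pytest.mark.parametrize("R, baseline", [(2, False), (2, True), (4, False), (4, True)])
    def test_matches_brute_force_per_alias_set_solve(self, rng, R, baseline):
        """Vectorized filter equals explicit per-set regularized LS (<= 1e-8)."""
        n_pe, T = 8, 4
        imgs, k = _lattice_series(rng, n_pe=n_pe, T=T, n_ro=2, E=2)
        pat = make_kt_pattern(n_pe, T, R)
        ku = undersample(k, pat)
        theta2 = rng.uniform(0.05, 2.0, size=(2, n_pe, T))
        psi = 0.3
        out = reconstruct_ktblast(ku, pat, SignalVarianceMap(theta2, psi), baseline_correction=baseline)
        oracle = _oracle_reconstruct(ku.data, pat.mask(), theta2, psi, baseline=baseline)
        assert np.max(np.abs(out - oracle)) < 1e-8

    def test_energy_non_amplification(self, rng):
        """Predicted aliased signal of the estimate never exceeds the measurement."""
        n_pe, T, R = 8, 4, 2
        imgs, k = _lattice_series(rng, n_pe=n_pe, T=T)
        pat = make_kt_pattern(n_pe, T, R)
        ku = undersample(k, pat)
        theta2 = rng.uniform(0.0, 2.0, size=(2, n_pe, T))
        psi = 0.2
        out = reconstruct_ktblast(ku, pat, SignalVarianceMap(theta2, psi), baseline_correction=False)
        from ktblast_tpm.ktblast import _to_xf

        shifts, weights = alias_kernel(pat)
        est_xf = _to_xf(out)
        meas_xf = _to_xf(kspace_to_image(ku.data))
        dy = n_pe // R
        for y0 in range(dy):
            for f0 in range(T):
                pred = sum(
                    w * est_xf[..., (y0 - s[0]) % n_pe, (f0 - s[1]) % T]
                    for s, w in zip(shifts, weights)
                )
                meas = meas_xf[..., y0, f0]
                assert np.all(np.abs(pred) <= np.abs(meas) + 1e-12)

    def test_mismatched_pattern_rejected(self, rng):
        _, k = _lattice_series(rng)
        pat = make_kt_pattern(8, 4, 2)
        svm = SignalVarianceMap(np.ones((2, 8, 4)), psi=0.1)
        with pytest.raises(ValueError):
            reconstruct_ktblast(k, pat, svm)  # data not undersampled


class TestReconstructorEstimator:
    def test_sklearn_param_interface(self):
        rec = KTBlastReconstructor(psi=0.5)
        assert rec.get_params()["psi"] == 0.5
        rec.set_params(psi=1.0, f_boxcar=3)
        assert rec.psi == 1.0 and rec.f_boxcar == 3

    def test_transform_before_fit_raises(self, rng):
        _, k = _lattice_series(rng)
        with pytest.raises(RuntimeError):
            KTBlastReconstructor().transform(k)

    def test_fit_transform_pipeline_on_phantom(self, small_phantom):
        """Static pixels reconstruct with error at the noise level for R = 2."""
        enc = encode_velocity(small_phantom)
        noise_sd = 0.01
        k = to_kspace(enc, noise_sd, rng=3)
        pat = make_kt_pattern(48, 12, 2)
        ku = undersample(k, pat)
        tr = acquire_training(k, 11)
        rec = KTBlastReconstructor().fit(tr)
        out = rec.transform(ku)
        assert rec.psi_ > 0
        static = small_phantom.static_mask
        err = np.abs(out[0, 0][static] - enc.images[0, 0][static])
        assert np.median(err) < 5 * noise_sd

    def test_psi_estimate_positive_on_noisy_data(self, small_encoded):
        k = to_kspace(small_encoded, noise_sd=0.05, rng=1)
        psi = estimate_noise_psi(k)
        assert 0.5 * 0.05**2 < psi < 5 * 0.05**2


class TestTemporalSmoothing:
    def test_peak_attenuation_non_increasing_in_R(self):
        """Sharp-peak phantom: reconstructed peak magnitude does not grow with R."""
        motion = MotionModel()
        n_pe = n_ro = 36
        T = 12
        ph = build_phantom(motion=motion, n_phases=T, matrix=(n_ro, n_pe))
        enc = encode_velocity(ph)
        k = to_kspace(enc, noise_sd=0.005, rng=11)
        peaks = []
        for R in (1, 2, 4, 6):
            if R == 1:
                out = reconstruct_full(k)
            else:
                pat = make_kt_pattern(n_pe, T, R)
                ku = undersample(k, pat)
                out = KTBlastReconstructor(psi=None).fit(acquire_training(k, 11)).transform(ku)
            # peak longitudinal phase signal over myocardium at the systolic phase
            from ktblast_tpm.quantify import phase_to_velocity

            t_sys = int(np.argmin(np.abs(ph.times_frac - motion.t_sys_peak)))
            v = phase_to_velocity(out[0, t_sys], out[3, t_sys], 30.0)
            peaks.append(np.nanmean(np.abs(v[ph.myo_mask[t_sys]])))
        assert all(p1 >= p2 - 0.15 for p1, p2 in zip(peaks, peaks[1:]))
        assert peaks[0] > peaks[-1]
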