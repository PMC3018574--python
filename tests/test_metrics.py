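"""Resolution matrix, PSF/CTF extraction, and the DLE/SD/OA metrics."""

import numpy as np
import pytest

import megres as m
from conftest import line_source_space, make_noise, random_spd, random_system


def build_ops(L, noise, lam):
    mne = m.mne_operator(L, noise, lambda_value=lam)
    dspm = m.apply_normalization(mne, m.dspm_weights(mne, noise), "dSPM")
    slor = m.apply_normalization(mne, m.sloreta_weights(mne, L), "sLORETA")
    return mne, dspm, slor


class TestResolutionMatrix:
    def test_inverse_leadfield_gives_identity(self):
        rng = np.random.default_rng(0)
        Lm = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        op = m.InverseOperator(matrix=np.linalg.inv(Lm), method="MNE",
                               lambda_value=0.0, snr=1.0, weights=np.ones(4))
        R = m.resolution_matrix(op, m.Leadfield(matrix=Lm))
        np.testing.assert_allclose(R.matrix, np.eye(4), atol=1e-12)

    def test_columns_equal_operator_applied_to_leadfield_columns(self):
        L, noise, _ = random_system(seed=1)
        mne, _, _ = build_ops(L, noise, lam=0.3)
        R = m.resolution_matrix(mne, L)
        for j in range(L.n_sources):
            psf_j = m.apply_inverse(mne, L.matrix[:, j])
            np.testing.assert_allclose(R.matrix[:, j], psf_j, rtol=1e-12,
                                       atol=1e-14)

    def test_mne_resolution_matrix_symmetric(self, physical_system):
        _, src, L, cov = physical_system
        lam = m.regularization_lambda(L, cov, snr=3.0)
        mne = m.mne_operator(L, cov, lambda_value=lam)
        R = m.resolution_matrix(mne, L)
        assert R.symmetry_residual() < 1e-10

    def test_shape_mismatch_rejected(self):
        op = m.InverseOperator(matrix=np.ones((3, 4)), method="MNE",
                               lambda_value=0.0, snr=1.0, weights=np.ones(3))
        with pytest.raises(ValueError):
            m.resolution_matrix(op, m.Leadfield(matrix=np.ones((5, 3))))


class TestPsfCtf:
    def test_identity_resolution_gives_deltas(self):
        R = m.ResolutionMatrix(matrix=np.eye(4), method="MNE")
        np.testing.assert_array_equal(m.psf(R, 2), np.eye(4)[:, 2])
        np.testing.assert_array_equal(m.ctf(R, 1), np.eye(4)[1, :])
        with pytest.raises(IndexError):
            m.psf(R, 4)
        with pytest.raises(IndexError):
            m.ctf(R, -1)

    def test_mne_psf_equals_ctf(self):
        L, noise, _ = random_system(seed=2)
        mne, _, _ = build_ops(L, noise, lam=0.3)
        R = m.resolution_matrix(mne, L)
        scale = np.abs(R.matrix).max()
        for i in range(R.n_sources):
            np.testing.assert_allclose(m.psf(R, i), m.ctf(R, i),
                                       atol=1e-10 * scale)

    def test_dspm_psf_is_weighted_mne_psf(self):
        L, noise, _ = random_system(seed=3)
        mne, dspm, _ = build_ops(L, noise, lam=0.3)
        w = dspm.weights
        R_mne = m.resolution_matrix(mne, L)
        R_dspm = m.resolution_matrix(dspm, L)
        for i in range(R_mne.n_sources):
            np.testing.assert_allclose(m.psf(R_dspm, i), w * m.psf(R_mne, i),
                                       rtol=1e-12, atol=1e-14)

    def test_normalized_ctfs_parallel_to_mne_ctfs(self):
        L, noise, _ = random_system(seed=4)
        mne, dspm, slor = build_ops(L, noise, lam=0.3)
        R_mne = m.resolution_matrix(mne, L)
        for op in (dspm, slor):
            R_w = m.resolution_matrix(op, L)
            for i in range(R_mne.n_sources):
                a, b = m.ctf(R_w, i), m.ctf(R_mne, i)
                cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                assert cos == pytest.approx(1.0, abs=1e-12)


class TestDle:
    def test_delta_distribution_zero_error(self):
        src = line_source_space()
        f = np.array([0.0, 1.0, 0.0])
        assert m.dle(f, 1, src) == 0.0

    def test_forced_arithmetic_collinear(self):
        src = line_source_space(spacing_cm=1.0, n=3)  # sources at 0, 1, 2 cm
        assert m.dle(np.array([0.1, 0.2, 1.0]), 0, src) == pytest.approx(2.0)

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(5)
        src = m.make_source_space(30, 0.09, 0.03, 6, seed=5)
        for _ in range(20):
            f = rng.normal(size=30)
            peak, best = None, -1.0
            for j in range(30):
                if abs(f[j]) > best:
                    best, peak = abs(f[j]), j
            delta = src.positions[peak] - src.positions[7]
            expected = 100.0 * np.sqrt((delta**2).sum())
            assert m.dle(f, 7, src) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.dle(np.zeros(3), 0, line_source_space())


class TestSd:
    def test_delta_distribution_zero_spread(self):
        assert m.sd(np.array([0.0, 1.0, 0.0]), 1, line_source_space()) == 0.0

    def test_forced_arithmetic_two_sources(self):
        src = line_source_space(spacing_cm=1.0, n=2)
        assert m.sd(np.array([1.0, 1.0]), 0, src) == pytest.approx(np.sqrt(0.5))

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(6)
        src = m.make_source_space(25, 0.09, 0.03, 6, seed=6)
        for _ in range(20):
            f = rng.normal(size=25)
            num = den = 0.0
            for j in range(25):
                d = 100.0 * np.linalg.norm(src.positions[j] - src.positions[4])
                num += d * f[j] ** 2
                den += f[j] ** 2
            assert m.sd(f, 4, src) == pytest.approx(np.sqrt(num / den), rel=1e-12)

    def test_weight_exponent_one(self):
        src = line_source_space(spacing_cm=1.0, n=2)
        # |F| weighting: sqrt((0*1 + 1*2) / 3) with F = (1, 2)
        val = m.sd(np.array([1.0, 2.0]), 0, src, weight_exponent=1)
        assert val == pytest.approx(np.sqrt(2.0 / 3.0))


class TestOa:
    def test_forced_and_zero(self):
        assert m.oa(np.array([1.0, -2.0, 3.0])) == 6.0
        assert m.oa(np.zeros(4)) == 0.0

    def test_matches_loop(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=50)
        assert m.oa(f) == pytest.approx(sum(abs(v) for v in f), rel=1e-14)


class TestMetricMaps:
    def test_identity_resolution_matrix(self):
        src = m.make_source_space(10, 0.09, 0.03, 6, seed=8)
        R = m.ResolutionMatrix(matrix=np.eye(10), method="MNE")
        for mode in ("PSF", "CTF"):
            maps = m.metric_maps(R, mode, src)
            np.testing.assert_array_equal(maps.dle, np.zeros(10))
            np.testing.assert_array_equal(maps.sd, np.zeros(10))
            np.testing.assert_array_equal(maps.oa, np.ones(10))

    def test_maps_agree_with_per_source_metrics(self):
        L, noise, src = random_system(seed=9)
        mne, _, _ = build_ops(L, noise, lam=0.3)
        R = m.resolution_matrix(mne, L)
        maps = m.metric_maps(R, "PSF", src)
        oa_raw = np.array([m.oa(m.psf(R, i)) for i in range(src.n_sources)])
        for i in range(src.n_sources):
            f = m.psf(R, i)
            assert maps.dle[i] == pytest.approx(m.dle(f, i, src), rel=1e-12)
            assert maps.sd[i] == pytest.approx(m.sd(f, i, src), rel=1e-12)
            assert maps.oa[i] == pytest.approx(oa_raw[i] / oa_raw.max(), rel=1e-12)

    def test_oa_normalized_max_exactly_one(self):
        L, noise, src = random_system(seed=10)
        mne, _, _ = build_ops(L, noise, lam=0.3)
        maps = m.metric_maps(m.resolution_matrix(mne, L), "CTF", src)
        assert maps.oa.max() == 1.0

    def test_mne_psf_maps_equal_ctf_maps(self):
        L, noise, src = random_system(seed=11)
        mne, _, _ = build_ops(L, noise, lam=0.3)
        R = m.resolution_matrix(mne, L)
        p_maps = m.metric_maps(R, "PSF", src)
        c_maps = m.metric_maps(R, "CTF", src)
        np.testing.assert_allclose(p_maps.dle, c_maps.dle, atol=1e-10)
        np.testing.assert_allclose(p_maps.sd, c_maps.sd, rtol=1e-10)
        np.testing.assert_allclose(p_maps.oa, c_maps.oa, rtol=1e-10)

    def test_ctf_maps_method_invariant(self):
        L, noise, src = random_system(seed=12)
        ops = build_ops(L, noise, lam=0.3)
        maps = [m.metric_maps(m.resolution_matrix(op, L), "CTF", src) for op in ops]
        for other in maps[1:]:
            np.testing.assert_allclose(maps[0].dle, other.dle, atol=1e-10)
            np.testing.assert_allclose(maps[0].sd, other.sd, rtol=1e-10)

    def test_sloreta_psf_peaks_at_true_source(self):
        L, noise, src = random_system(seed=13, n_ch=10, n_src=25)
        _, _, slor = build_ops(L, noise, lam=0.3)
        maps = m.metric_maps(m.resolution_matrix(slor, L), "PSF", src)
        assert maps.dle.max() == 0.0

    def test_near_identity_limit_all_methods(self):
        # square full-rank system, vanishing regularization: R -> I
        rng = np.random.default_rng(14)
        src = m.make_source_space(8, 0.09, 0.03, 6, seed=14)
        Lm = rng.normal(size=(8, 8)) + 8 * np.eye(8)
        L = m.Leadfield(matrix=Lm)
        noise = make_noise(random_spd(rng, 8))
        lam = 1e-14 * float((Lm**2).sum())
        for op in build_ops(L, noise, lam):
            R = m.resolution_matrix(op, L)
            for mode in ("PSF", "CTF"):
                maps = m.metric_maps(R, mode, src)
                np.testing.assert_array_equal(maps.dle, np.zeros(8))
                assert maps.sd.max() < 1e-3
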