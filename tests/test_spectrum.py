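import math

import numpy as np
import pytest

from saliencywave.spectrum import (
    WaveletFilterPair,
    conspicuity_map,
    dct2_forward,
    dct2_inverse,
    mallat_decompose,
    mallat_reconstruct,
    max_feasible_depth,
    multiscale_magnitudes,
    split_magnitude_sign,
)

HAAR = WaveletFilterPair.from_name("haar")


# ---------------------------------------------------------------------------
# Independent oracles

def dct2_oracle(x):
    """O(N^4) basis-projection oracle for the orthonormal 2-D DCT-II."""
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    out = np.zeros((m, n))
    for p in range(m):
        for q in range(n):
            ap = math.sqrt(1 / m) if p == 0 else math.sqrt(2 / m)
            aq = math.sqrt(1 / n) if q == 0 else math.sqrt(2 / n)
            acc = 0.0
            for i in range(m):
                for j in range(n):
                    acc += (
                        x[i, j]
                        * math.cos(math.pi * (2 * i + 1) * p / (2 * m))
                        * math.cos(math.pi * (2 * j + 1) * q / (2 * n))
                    )
            out[p, q] = ap * aq * acc
    return out


def haar_depth1_oracle(x):
    """Direct convolve-and-downsample Haar analysis (periodic, 1 level)."""
    x = np.asarray(x, dtype=float)
    s = 1 / math.sqrt(2)

    def analyze_rows(m):
        n = m.shape[0]
        lo = np.zeros((n // 2, m.shape[1]))
        hi = np.zeros_like(lo)
        for i in range(n // 2):
            a, b = m[2 * i % n], m[(2 * i + 1) % n]
            lo[i] = s * (a + b)
            hi[i] = s * (a - b)
        return lo, hi

    sr, dr = analyze_rows(x)
    bss, bsd = (t.T for t in analyze_rows(sr.T))
    bds, bdd = (t.T for t in analyze_rows(dr.T))
    return bss, bds, bsd, bdd


def block_mean_oracle(x, block):
    """Piecewise-constant block-average of a matrix."""
    h, w = x.shape
    out = np.empty_like(x, dtype=float)
    for i in range(0, h, block):
        for j in range(0, w, block):
            out[i : i + block, j : j + block] = x[
                i : i + block, j : j + block
            ].mean()
    return out


# ---------------------------------------------------------------------------
# DCT

class TestDct:
    def test_constant_is_dc_only(self):
        F = dct2_forward(np.ones((2, 2)))
        assert F[0, 0] == pytest.approx(2.0)
        assert np.abs(F).sum() == pytest.approx(2.0)

    def test_round_trip(self, rng):
        x = rng.normal(size=(16, 16))
        np.testing.assert_allclose(dct2_inverse(dct2_forward(x)), x, atol=1e-10)

    def test_small_case_against_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        expected = dct2_oracle(x)
        # frozen oracle output for this matrix
        np.testing.assert_allclose(
            expected, [[5.0, -1.0], [-2.0, 0.0]], atol=1e-12
        )
        np.testing.assert_allclose(dct2_forward(x), expected, atol=1e-10)

    @pytest.mark.parametrize("m", range(1, 9))
    @pytest.mark.parametrize("n", range(1, 9))
    def test_all_small_sizes_against_oracle(self, m, n):
        x = np.random.default_rng(m * 10 + n).normal(size=(m, n))
        np.testing.assert_allclose(dct2_forward(x), dct2_oracle(x), atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dct2_forward(np.zeros((0, 4)))


class TestSplitMagnitudeSign:
    def test_elementwise_definition(self):
        pair = split_magnitude_sign(np.array([[2.0, -3.0], [0.0, 1.0]]))
        np.testing.assert_array_equal(pair.A_M, [[2, 3], [0, 1]])
        np.testing.assert_array_equal(pair.S_M, [[1, -1], [0, 1]])

    def test_reassembles_exactly(self, rng):
        F = rng.normal(size=(12, 9))
        F[0, 3] = 0.0
        pair = split_magnitude_sign(F)
        np.testing.assert_array_equal(pair.S_M * pair.A_M, F)
        assert pair.A_M.min() >= 0

    def test_all_negative(self):
        F = -np.ones((3, 3))
        pair = split_magnitude_sign(F)
        assert np.all(pair.S_M == -1)
        np.testing.assert_array_equal(pair.A_M, -F)


# ---------------------------------------------------------------------------
# Mallat filter bank

class TestMallat:
    def test_haar_constant_depth1(self):
        pyr = mallat_decompose(np.full((8, 8), 3.0), 1, HAAR)
        bds, bsd, bdd = pyr.details[0]
        assert np.allclose(pyr.approx, 6.0)  # DC gain 2 per 2-D level
        assert np.allclose(bds, 0) and np.allclose(bsd, 0) and np.allclose(bdd, 0)

    @pytest.mark.parametrize("name", ["haar", "db2"])
    @pytest.mark.parametrize("depth", [1, 2, 3, 4, 5, 6])
    def test_perfect_reconstruction(self, rng, name, depth):
        filters = WaveletFilterPair.from_name(name)
        x = rng.normal(size=(64, 64))
        rec = mallat_reconstruct(mallat_decompose(x, depth, filters))
        np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_perfect_reconstruction_non_pow2(self, rng):
        x = rng.normal(size=(37, 53))
        rec = mallat_reconstruct(mallat_decompose(x, 3, HAAR))
        np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_depth1_haar_against_filter_bank_oracle(self, rng):
        x = rng.normal(size=(2, 2))
        pyr = mallat_decompose(x, 1, HAAR)
        bss, bds, bsd, bdd = haar_depth1_oracle(x)
        np.testing.assert_allclose(pyr.approx, bss, atol=1e-12)
        np.testing.assert_allclose(pyr.details[0][0], bds, atol=1e-12)
        np.testing.assert_allclose(pyr.details[0][1], bsd, atol=1e-12)
        np.testing.assert_allclose(pyr.details[0][2], bdd, atol=1e-12)

    def test_depth1_haar_oracle_larger(self, rng):
        x = rng.normal(size=(8, 6))
        pyr = mallat_decompose(x, 1, HAAR)
        bss, bds, bsd, bdd = haar_depth1_oracle(x)
        np.testing.assert_allclose(pyr.approx, bss, atol=1e-12)
        np.testing.assert_allclose(pyr.details[0][2], bdd, atol=1e-12)

    def test_subband_shapes_halve(self, rng):
        pyr = mallat_decompose(rng.normal(size=(32, 32)), 3, HAAR)
        shapes = [d[0].shape for d in pyr.details]
        assert shapes == [(16, 16), (8, 8), (4, 4)]
        assert pyr.approx.shape == (4, 4)

    def test_zeroed_details_give_block_means(self, rng):
        # Haar approx-only reconstruction == 2x2 block averaging
        x = rng.normal(size=(16, 16))
        pyr = mallat_decompose(x, 1, HAAR)
        pyr.details[0] = tuple(np.zeros_like(b) for b in pyr.details[0])
        np.testing.assert_allclose(
            mallat_reconstruct(pyr), block_mean_oracle(x, 2), atol=1e-10
        )

    def test_all_subbands_zero_gives_zero(self, rng):
        pyr = mallat_decompose(rng.normal(size=(16, 16)), 2, HAAR)
        pyr.approx = np.zeros_like(pyr.approx)
        pyr.details = [
            tuple(np.zeros_like(b) for b in lvl) for lvl in pyr.details
        ]
        np.testing.assert_allclose(mallat_reconstruct(pyr), 0.0, atol=1e-12)

    def test_depth_too_large_names_max(self):
        with pytest.raises(ValueError, match="max feasible depth is 3"):
            mallat_decompose(np.zeros((8, 8)), 4, HAAR)

    def test_mismatched_subbands_rejected(self, rng):
        pyr = mallat_decompose(rng.normal(size=(16, 16)), 1, HAAR)
        pyr.details[0] = (
            np.zeros((4, 4)),
            pyr.details[0][1],
            pyr.details[0][2],
        )
        with pytest.raises(ValueError, match="subband"):
            mallat_reconstruct(pyr)

    def test_unknown_wavelet(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            WaveletFilterPair.from_name("sym9")

    def test_max_feasible_depth(self):
        assert max_feasible_depth((128, 128)) == 7
        assert max_feasible_depth((128, 64)) == 6
        assert max_feasible_depth((1, 100)) == 0


# ---------------------------------------------------------------------------
# Multiscale magnitude modulation

class TestMultiscaleMagnitudes:
    def test_returns_requested_count(self, rng):
        A = np.abs(rng.normal(size=(64, 64)))
        assert multiscale_magnitudes(A, 6).n_scales == 6

    @pytest.mark.parametrize("domain", ["log", "linear"])
    def test_gain_one_is_identity(self, rng, domain):
        A = np.abs(rng.normal(size=(32, 32)))
        for Ap in multiscale_magnitudes(A, 4, approx_gain=1.0, domain=domain):
            np.testing.assert_allclose(Ap, A, atol=1e-8)

    def test_constant_fully_suppressed_linear(self):
        A = np.full((16, 16), 5.0)
        for Ap in multiscale_magnitudes(A, 3, approx_gain=0.0, domain="linear"):
            np.testing.assert_allclose(Ap, 0.0, atol=1e-10)

    def test_constant_whitens_to_unity_log(self):
        # log-domain whitening divides by the envelope: flat spectrum -> 1
        A = np.full((16, 16), 5.0)
        for Ap in multiscale_magnitudes(A, 3, approx_gain=0.0, domain="log"):
            np.testing.assert_allclose(Ap, 1.0, atol=1e-6)

    def test_linear_mode_is_linear(self, rng):
        A = np.abs(rng.normal(size=(16, 16)))
        a = 3.7
        left = multiscale_magnitudes(a * A, 3, domain="linear")
        right = multiscale_magnitudes(A, 3, domain="linear")
        for la, ra in zip(left, right):
            np.testing.assert_allclose(la, a * ra, atol=1e-8)

    def test_log_mode_scale_invariant(self, rng):
        # dividing by the envelope cancels any positive gain
        A = np.abs(rng.normal(size=(16, 16))) + 0.1
        left = multiscale_magnitudes(7.3 * A, 3, domain="log")
        right = multiscale_magnitudes(A, 3, domain="log")
        for la, ra in zip(left, right):
            np.testing.assert_allclose(la, ra, rtol=1e-6)

    def test_monotone_energy_retention_linear(self, rng):
        # coarser approximations carry less energy on 1/f-like magnitudes
        from conftest import one_over_f_noise

        A = np.abs(
            np.fft.fft2(one_over_f_noise(rng, 64))[:32, :32]
        )
        energies = [
            (Ap**2).sum()
            for Ap in multiscale_magnitudes(A, 5, domain="linear")
        ]
        assert all(b >= a - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_too_many_scales_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            multiscale_magnitudes(np.ones((8, 8)), 4)

    def test_bad_domain_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            multiscale_magnitudes(np.ones((8, 8)), 2, domain="sqrt")


class TestConspicuityMap:
    def test_unmodified_magnitude_recovers_channel(self, rng):
        channel = np.abs(rng.normal(size=(32, 32)))  # nonnegative
        pair = split_magnitude_sign(dct2_forward(channel))
        out = conspicuity_map(pair.A_M, pair.S_M)
        np.testing.assert_allclose(out, channel, atol=1e-8)

    def test_zero_magnitude_gives_zero(self):
        out = conspicuity_map(np.zeros((8, 8)), np.ones((8, 8)))
        np.testing.assert_array_equal(out, 0.0)

    def test_whitened_impulse_location_preserved(self):
        channel = np.full((64, 64), 0.2)
        channel[40, 23] = 1.0
        pair = split_magnitude_sign(dct2_forward(channel))
        out = conspicuity_map(np.ones_like(pair.A_M), pair.S_M)
        assert np.unravel_index(np.argmax(out), out.shape) == (40, 23)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            conspicuity_map(np.ones((4, 4)), np.ones((4, 5)))
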