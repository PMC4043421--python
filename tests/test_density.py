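import numpy as np
import pytest

from adakde.bandwidths import knn1_bandwidths, knn2_bandwidths
from adakde.density import (ChromInfo, DensityTrack, MixtureParams,
                            adaptive_kde, blend_uniform, evaluate_at,
                            fixed_kde, piecewise_constant_kde,
                            piecewise_linear_kde)
from adakde.kernels import KernelSpec, build_kernel

GAUSS = KernelSpec("gaussian")
SQUARE = KernelSpec("square")
TRIANGLE = KernelSpec("triangle")


def naive_density(x, h, spec, queries):
    """Per-query summation oracle using only the kernel weight function."""
    x = np.asarray(x)
    h = np.broadcast_to(np.asarray(h, dtype=float), x.shape)
    kernels = {hv: build_kernel(spec, hv) for hv in np.unique(h)}
    out = []
    for q in np.atleast_1d(queries):
        out.append(sum(kernels[hv].weight(int(q - xi)) for xi, hv in zip(x, h))
                   / len(x))
    return np.array(out)


class TestFixedKde:
    def test_single_point_square(self, chrom1k):
        t = fixed_kde([50], 1.0, SQUARE, chrom1k)
        assert t.start == 47
        np.testing.assert_allclose(t.values, np.full(7, 1 / 7), rtol=1e-15)
        assert t.value_at(46) == 0.0
        assert t.value_at(54) == 0.0

    def test_duplicate_points_collapse(self, chrom1k):
        for spec in (GAUSS, SQUARE, TRIANGLE):
            one = fixed_kde([50], 3.0, spec, chrom1k)
            two = fixed_kde([50, 50], 3.0, spec, chrom1k)
            np.testing.assert_allclose(two.values, one.values, rtol=1e-15)

    def test_empty_rejected(self, chrom1k):
        with pytest.raises(ValueError):
            fixed_kde([], 1.0, GAUSS, chrom1k)

    def test_matches_naive_oracle(self, rng):
        info = ChromInfo("chr1", 20_000)
        x = np.sort(rng.integers(1000, 19_000, size=100))
        t = fixed_kde(x, 16.0, GAUSS, info)
        q = rng.integers(1, 20_000, size=1000)
        expected = naive_density(x, 16.0, GAUSS, q)
        np.testing.assert_allclose(t.value_at(q), expected, atol=1e-10)


class TestAdaptiveKde:
    def test_constant_bandwidths_reduce_to_fixed(self, rng, chrom1k):
        x = np.sort(rng.integers(100, 900, size=30))
        fixed = fixed_kde(x, 8.0, TRIANGLE, chrom1k)
        adaptive = adaptive_kde(x, np.full(30, 8.0), TRIANGLE, chrom1k)
        assert fixed.start == adaptive.start
        np.testing.assert_array_equal(fixed.values, adaptive.values)

    def test_two_plateaus_enumeration(self):
        # h=2 -> radius 6: 13-bp plateau; h=500 -> radius 1500: 3001-bp
        # plateau; in the overlap the narrow kernel sits on the broad one
        info = ChromInfo("chr1", 100_000)
        t = adaptive_kde([3000, 4000], [2.0, 500.0], SQUARE, info)
        broad = 0.5 / 3001
        narrow = 0.5 / 13
        assert t.value_at(3000) == pytest.approx(broad + narrow, rel=1e-12)
        assert t.value_at(2994) == pytest.approx(broad + narrow, rel=1e-12)
        assert t.value_at(2993) == pytest.approx(broad, rel=1e-12)
        assert t.value_at(5500) == pytest.approx(broad, rel=1e-12)
        assert t.value_at(5501) == 0.0

    def test_length_mismatch(self, chrom1k):
        with pytest.raises(ValueError):
            adaptive_kde([10, 20], [1.0], GAUSS, chrom1k)

    @pytest.mark.parametrize("spec", [GAUSS, SQUARE, TRIANGLE])
    def test_matches_naive_oracle(self, rng, spec):
        info = ChromInfo("chr1", 10_000)
        x = np.sort(rng.integers(500, 9500, size=60))
        h = rng.integers(1, 50, size=60).astype(float)
        t = adaptive_kde(x, h, spec, info)
        q = rng.integers(1, 10_000, size=300)
        np.testing.assert_allclose(t.value_at(q), naive_density(x, h, spec, q),
                                   atol=1e-10)


class TestBlendUniform:
    def test_epsilon_zero_identity(self, chrom1k):
        t = fixed_kde([500], 4.0, GAUSS, chrom1k)
        b = blend_uniform(t, MixtureParams(epsilon=0.0, G=1000))
        np.testing.assert_array_equal(t.values, b.values)

    def test_epsilon_one_uniform(self, chrom1k):
        t = fixed_kde([500], 4.0, GAUSS, chrom1k)
        b = blend_uniform(t, MixtureParams(epsilon=1.0, G=1000))
        np.testing.assert_allclose(b.value_at([1, 500, 1000]), 0.001, rtol=1e-15)

    def test_arithmetic(self, chrom1k):
        t = DensityTrack(chrom_info=chrom1k, kind="dense", n_train=1,
                         start=10, values=np.array([0.01]))
        b = blend_uniform(t, MixtureParams(epsilon=0.1, G=1000))
        assert b.value_at(10) == pytest.approx(0.0091, rel=1e-14)

    def test_epsilon_out_of_range(self):
        with pytest.raises(ValueError):
            MixtureParams(epsilon=1.5, G=1000)


class TestEvaluateAt:
    def test_far_query_unblended_zero(self, chrom1k):
        params = MixtureParams(epsilon=0.0, G=1000)
        assert evaluate_at([50], [1.0], SQUARE, params, 900) == 0.0

    def test_far_query_blended_baseline(self):
        params = MixtureParams(epsilon=0.1, G=10 ** 6)
        v = evaluate_at([50], [1.0], SQUARE, params, 999_999)
        assert v == pytest.approx(1e-7, rel=1e-14)

    @pytest.mark.parametrize("spec", [GAUSS, SQUARE, TRIANGLE])
    def test_equals_dense_track(self, rng, spec):
        info = ChromInfo("chr1", 8000)
        x = np.sort(rng.integers(500, 7500, size=80))
        h = knn2_bandwidths(x, 3)
        track = blend_uniform(adaptive_kde(x, h, spec, info),
                              MixtureParams(epsilon=0.1, G=8000))
        q = rng.integers(1, 8000, size=500)
        got = evaluate_at(x, h, spec, MixtureParams(epsilon=0.1, G=8000), q)
        np.testing.assert_allclose(got, track.value_at(q), atol=1e-12)

    def test_query_outside_range_rejected(self):
        params = MixtureParams(epsilon=0.0, G=1000)
        with pytest.raises(ValueError):
            evaluate_at([50], [1.0], SQUARE, params, 1001)


class TestPiecewiseConstant:
    def test_single_point(self, chrom1k):
        t = piecewise_constant_kde([50], [1.0], SQUARE, chrom1k)
        nonzero = t.pieces[t.pieces[:, 2] > 0]
        np.testing.assert_allclose(nonzero, [[47, 53, 1 / 7]], rtol=1e-15)

    def test_two_overlapping_kernels_by_hand(self, chrom1k):
        # supports 47..53 and 49..55: heights 1/14, 2/14, 1/14
        t = piecewise_constant_kde([50, 52], [1.0, 1.0], SQUARE, chrom1k)
        nz = t.pieces[t.pieces[:, 2] > 0]
        np.testing.assert_allclose(
            nz, [[47, 48, 1 / 14], [49, 53, 2 / 14], [54, 55, 1 / 14]],
            rtol=1e-14)

    def test_piece_count_bound(self, rng):
        info = ChromInfo("chr1", 50_000)
        x = np.sort(rng.integers(100, 49_000, size=200))
        h = knn1_bandwidths(x, 2)
        t = piecewise_constant_kde(x, h, SQUARE, info)
        assert len(t.pieces) <= 2 * len(x) + 1

    def test_non_square_rejected(self, chrom1k):
        with pytest.raises(ValueError):
            piecewise_constant_kde([50], [1.0], GAUSS, chrom1k)

    @pytest.mark.parametrize("seed", range(5))
    def test_pointwise_equals_dense(self, seed):
        rng = np.random.default_rng(seed)
        info = ChromInfo("chr1", 30_000)
        x = np.sort(rng.integers(200, 29_000, size=70))
        h = rng.integers(1, 80, size=70).astype(float)
        pc = piecewise_constant_kde(x, h, SQUARE, info)
        dense = adaptive_kde(x, h, SQUARE, info)
        q = np.arange(dense.start, dense.end + 1)
        np.testing.assert_allclose(pc.value_at(q), dense.values, atol=1e-15)

    def test_construction_independent_of_genome_size(self, rng):
        x = np.sort(rng.integers(100, 9000, size=50))
        h = np.full(50, 4.0)
        small = piecewise_constant_kde(x, h, SQUARE, ChromInfo("c", 10_000))
        huge = piecewise_constant_kde(x, h, SQUARE, ChromInfo("c", 10 ** 9))
        np.testing.assert_array_equal(small.pieces, huge.pieces)


class TestPiecewiseLinear:
    def test_single_point_breakpoints(self, chrom1k):
        t = piecewise_linear_kde([50], [1.0], TRIANGLE, chrom1k)
        np.testing.assert_allclose(
            t.breakpoints, [[44, 0.0], [50, 1 / 6], [56, 0.0]], atol=1e-15)

    def test_disjoint_superposition_six_breakpoints(self, chrom1k):
        t = piecewise_linear_kde([50, 200], [1.0, 1.0], TRIANGLE, chrom1k)
        assert t.breakpoints.shape == (6, 2)
        assert t.value_at(50) == pytest.approx(1 / 12, rel=1e-12)
        assert t.value_at(120) == 0.0

    def test_non_triangle_rejected(self, chrom1k):
        with pytest.raises(ValueError):
            piecewise_linear_kde([50], [1.0], SQUARE, chrom1k)

    @pytest.mark.parametrize("seed", range(5))
    def test_interpolation_equals_dense(self, seed):
        rng = np.random.default_rng(seed)
        info = ChromInfo("chr1", 30_000)
        x = np.sort(rng.integers(500, 29_000, size=70))
        # non-integer bandwidths exercise the support-edge discontinuity
        h = rng.uniform(0.6, 60, size=70)
        pl = piecewise_linear_kde(x, h, TRIANGLE, info)
        dense = adaptive_kde(x, h, TRIANGLE, info)
        q = np.arange(dense.start, dense.end + 1)
        np.testing.assert_allclose(pl.value_at(q), dense.values, atol=1e-9)


class TestMassConservation:
    @pytest.mark.parametrize("spec", [GAUSS, SQUARE, TRIANGLE])
    def test_unit_mass_random_instances(self, rng, spec):
        info = ChromInfo("chr1", 200_000)
        for _ in range(10):
            n = int(rng.integers(2, 60))
            x = np.sort(rng.integers(50_000, 150_000, size=n))
            h = rng.uniform(1, 300, size=n)
            t = adaptive_kde(x, h, spec, info)
            assert t.total_mass() == pytest.approx(1.0, abs=1e-6)
            b = blend_uniform(t, MixtureParams(epsilon=0.25, G=info.length))
            assert b.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_overhanging_kernel_mass_dropped(self):
        info = ChromInfo("chr1", 100)
        t = fixed_kde([1], 10.0, SQUARE, info)
        assert t.total_mass() < 1.0


class TestKnn2Positivity:
    @pytest.mark.parametrize("spec", [GAUSS, SQUARE, TRIANGLE])
    def test_positive_between_extremes_clustered(self, spec):
        rng = np.random.default_rng(7)
        for _ in range(25):
            clusters = []
            pos = 1000
            for _ in range(int(rng.integers(2, 5))):
                pos += int(rng.integers(2000, 30_000))
                clusters.append(pos + np.sort(rng.integers(0, 80,
                                                           rng.integers(4, 25))))
            x = np.sort(np.concatenate(clusters))
            k = int(rng.integers(1, 4))
            h = knn2_bandwidths(x, k)
            info = ChromInfo("chr1", int(x[-1]) + 1000)
            t = adaptive_kde(x, h, spec, info)
            inner = t.value_at(np.arange(x[0], x[-1] + 1))
            assert inner.min() > 0.0
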