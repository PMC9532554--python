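"""Grid types, trilinear sampling, warping, and resolution changes."""

import numpy as np
import pytest

import proreg as pr
from proreg.grids import downsample_labels


def ramp_volume(shape, a=1.0, b=2.0, c=3.0, d=-1.0):
    """f(x, y, z) = a + b*x + c*y + d*z on the voxel lattice."""
    x, y, z = np.meshgrid(*(np.arange(n, dtype=np.float32) for n in shape),
                          indexing="ij")
    return pr.Volume(a + b * x + c * y + d * z)


class TestTypes:
    def test_volume_rejects_nonfinite_and_tiny(self):
        with pytest.raises(ValueError):
            pr.Volume(np.full((4, 4, 4), np.nan))
        with pytest.raises(ValueError):
            pr.Volume(np.zeros((1, 4, 4)))

    def test_flow_shape_contract(self):
        with pytest.raises(ValueError):
            pr.Flow(np.zeros((2, 4, 4, 4)))
        u = pr.Flow.zeros((4, 5, 6))
        assert u.spatial_shape == (4, 5, 6)

    def test_labelmap_ids_sorted_nonzero(self):
        lm = pr.LabelMap(np.array([[[0, 3], [1, 1]], [[0, 0], [3, 2]]]))
        assert list(lm.label_ids) == [1, 2, 3]


class TestTrilinearSample:
    def test_lattice_identity(self):
        rng = np.random.default_rng(0)
        v = pr.Volume(rng.uniform(0, 255, size=(5, 6, 7)))
        pts = np.stack(np.meshgrid(*(np.arange(n) for n in v.shape),
                                   indexing="ij"), -1).reshape(-1, 3)
        np.testing.assert_allclose(pr.trilinear_sample(v, pts),
                                   v.data.ravel(), rtol=0, atol=0)

    def test_midpoint_between_adjacent_voxels(self):
        data = np.zeros((2, 2, 2), dtype=np.float32)
        data[1, 0, 0] = 10.0
        v = pr.Volume(data)
        assert pr.trilinear_sample(v, [[0.5, 0.0, 0.0]])[0] == pytest.approx(5.0)

    def test_reproduces_trilinear_functions(self):
        # trilinear interpolation is exact on f = a + bx + cy + dz
        v = ramp_volume((6, 6, 6), a=1.0, b=2.0, c=3.0, d=-1.0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0.0, 5.0, size=(100, 3))
        expected = 1.0 + 2.0 * pts[:, 0] + 3.0 * pts[:, 1] - pts[:, 2]
        np.testing.assert_allclose(pr.trilinear_sample(v, pts), expected,
                                   atol=1e-5)

    def test_out_of_hull_clamps_to_edge(self):
        v = ramp_volume((4, 4, 4), a=0.0, b=1.0, c=0.0, d=0.0)
        got = pr.trilinear_sample(v, [[-3.0, 1.0, 1.0], [99.0, 1.0, 1.0]])
        np.testing.assert_allclose(got, [0.0, 3.0], atol=1e-6)

    def test_nonfinite_points_rejected(self):
        v = ramp_volume((4, 4, 4))
        with pytest.raises(ValueError):
            pr.trilinear_sample(v, [[np.nan, 0, 0]])


class TestWarpImage:
    def test_zero_flow_is_identity(self):
        rng = np.random.default_rng(2)
        m = pr.Volume(rng.uniform(0, 255, size=(8, 8, 8)))
        w = pr.warp_image(m, pr.Flow.zeros(m.shape))
        np.testing.assert_array_equal(w.data, m.data)

    def test_integer_translation(self):
        rng = np.random.default_rng(3)
        m = pr.Volume(rng.uniform(0, 255, size=(8, 8, 8)))
        u = pr.Flow(np.zeros((3, 8, 8, 8), dtype=np.float32))
        u.data[0] = 1.0
        w = pr.warp_image(m, u)
        # interior: warped(x) = m(x + 1 along axis 0); boundary clamps
        np.testing.assert_allclose(w.data[:-1], m.data[1:], atol=1e-5)
        np.testing.assert_allclose(w.data[-1], m.data[-1], atol=1e-5)

    def test_exact_on_linear_image(self):
        from proreg.phantoms import DeformationSpec, random_smooth_flow
        shape = (10, 10, 10)
        m = ramp_volume(shape, a=0.0, b=1.0, c=0.0, d=0.0)  # f = x
        u = random_smooth_flow(shape, DeformationSpec(amplitude=1.2,
                                                      smoothness_sigma=2.0, seed=4))
        w = pr.warp_image(m, u)
        x = np.arange(shape[0], dtype=np.float32)[:, None, None]
        expected = np.clip(x + u.data[0], 0, shape[0] - 1)
        np.testing.assert_allclose(w.data, expected, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pr.warp_image(pr.Volume(np.zeros((4, 4, 4))), pr.Flow.zeros((5, 5, 5)))

    def test_counts_one_interpolation_per_call(self):
        pr.counters.reset()
        m = pr.Volume(np.zeros((4, 4, 4)))
        w1 = pr.warp_image(m, pr.Flow.zeros(m.shape))
        w2 = pr.warp_image(w1, pr.Flow.zeros(m.shape))
        assert pr.counters.warp_calls == 2
        assert (m.interp_count, w1.interp_count, w2.interp_count) == (0, 1, 2)


class TestWarpLabels:
    def test_zero_flow_identity_and_translation(self):
        rng = np.random.default_rng(5)
        lm = pr.LabelMap(rng.integers(0, 4, size=(8, 8, 8)))
        same = pr.warp_labels(lm, pr.Flow.zeros(lm.shape))
        np.testing.assert_array_equal(same.data, lm.data)
        u = pr.Flow(np.zeros((3, 8, 8, 8), dtype=np.float32))
        u.data[0] = 1.0
        shifted = pr.warp_labels(lm, u)
        np.testing.assert_array_equal(shifted.data[:-1], lm.data[1:])

    def test_half_voxel_ties_round_up(self):
        # floor(x + 0.5) at displacement exactly 0.5 picks the upper voxel;
        # verified against a brute-force per-voxel oracle
        rng = np.random.default_rng(6)
        lm = pr.LabelMap(rng.integers(0, 5, size=(6, 6, 6)))
        u = pr.Flow(rng.uniform(-1, 1, size=(3, 6, 6, 6)).astype(np.float32))
        u.data[0, 2, 3, 1] = 0.5  # exact tie somewhere
        got = pr.warp_labels(lm, u)
        expected = np.empty_like(lm.data)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    idx = []
                    for ax, pos in enumerate((i, j, k)):
                        c = pos + float(u.data[ax, i, j, k])
                        idx.append(int(min(max(np.floor(c + 0.5), 0), 5)))
                    expected[i, j, k] = lm.data[idx[0], idx[1], idx[2]]
        np.testing.assert_array_equal(got.data, expected)

    def test_output_labels_subset_of_input(self):
        rng = np.random.default_rng(7)
        lm = pr.LabelMap(rng.integers(0, 6, size=(8, 8, 8)))
        u = pr.Flow(rng.uniform(-2, 2, size=(3, 8, 8, 8)).astype(np.float32))
        out = pr.warp_labels(lm, u)
        assert set(np.unique(out.data)) <= set(np.unique(lm.data)) | {0}


class TestResolutionChange:
    def test_downsample_constant_and_full_scale_brain_size(self):
        v = pr.Volume(np.full((8, 8, 8), 3.25, dtype=np.float32))
        d = pr.downsample_volume(v)
        assert d.shape == (4, 4, 4)
        np.testing.assert_allclose(d.data, 3.25)
        big = pr.Volume(np.zeros((192, 160, 192), dtype=np.float32) + 1.0)
        assert pr.downsample_volume(big).shape == (96, 80, 96)

    def test_downsample_ramp_block_means(self):
        v = ramp_volume((8, 8, 8), a=0.0, b=1.0, c=0.0, d=0.0)
        d = pr.downsample_volume(v)
        np.testing.assert_allclose(d.data[:, 0, 0], [0.5, 2.5, 4.5, 6.5])

    def test_downsample_odd_extent_rejected(self):
        with pytest.raises(ValueError):
            pr.downsample_volume(pr.Volume(np.zeros((6, 7, 8))))

    def test_downsample_labels_strided(self):
        lm = pr.LabelMap(np.arange(4 ** 3).reshape(4, 4, 4) % 3)
        d = downsample_labels(lm)
        np.testing.assert_array_equal(d.data, lm.data[::2, ::2, ::2])

    def test_upsample_flow_zero_and_constant(self):
        z = pr.upsample_flow(pr.Flow.zeros((8, 8, 8)))
        assert z.spatial_shape == (16, 16, 16)
        assert np.all(z.data == 0)
        u = pr.Flow(np.zeros((3, 8, 8, 8), dtype=np.float32))
        u.data[0], u.data[2] = 1.5, -2.0
        up = pr.upsample_flow(u)
        np.testing.assert_allclose(up.data[0], 3.0, atol=1e-6)
        np.testing.assert_allclose(up.data[1], 0.0, atol=1e-6)
        np.testing.assert_allclose(up.data[2], -4.0, atol=1e-6)

    def test_upsample_flow_linear_closed_form(self):
        # u0(x) = 0.1 x at low scale -> 0.2 * (low-scale coordinate of each
        # fine voxel), with the cell-aligned mapping x_low = x/2 - 0.25
        # clamped at the edges
        n = 8
        u = pr.Flow(np.zeros((3, n, n, n), dtype=np.float32))
        u.data[0] = 0.1 * np.arange(n, dtype=np.float32)[:, None, None]
        up = pr.upsample_flow(u)
        xf = np.arange(2 * n, dtype=np.float32)
        x_low = np.clip(xf / 2.0 - 0.25, 0, n - 1)
        np.testing.assert_allclose(up.data[0, :, 0, 0], 0.2 * x_low, atol=1e-5)
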