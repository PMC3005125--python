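"""Field algebra: warping, composition, exponentiation, Jacobians."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmorphons.fields import (
    DisplacementField,
    Volume,
    compose_fields,
    exp_field,
    jacobian_determinant,
    warp_field,
    warp_volume,
)


def constant_field(shape, vec):
    v = np.zeros(tuple(shape) + (len(vec),))
    v[...] = np.asarray(vec, dtype=float)
    return DisplacementField(v)


def loop_warp_2d(img, D):
    """Brute-force per-pixel bilinear interpolation with coordinate clamping."""
    out = np.empty_like(img)
    n0, n1 = img.shape
    for i in range(n0):
        for j in range(n1):
            x = min(max(i + D[i, j, 0], 0.0), n0 - 1.0)
            y = min(max(j + D[i, j, 1], 0.0), n1 - 1.0)
            i0, j0 = int(np.floor(x)), int(np.floor(y))
            i1, j1 = min(i0 + 1, n0 - 1), min(j0 + 1, n1 - 1)
            fx, fy = x - i0, y - j0
            out[i, j] = (
                img[i0, j0] * (1 - fx) * (1 - fy)
                + img[i1, j0] * fx * (1 - fy)
                + img[i0, j1] * (1 - fx) * fy
                + img[i1, j1] * fx * fy
            )
    return out


class TestWarpVolume:
    def test_zero_field_is_identity_bit_exact(self, random_volume):
        out = warp_volume(random_volume, DisplacementField.zeros(random_volume.shape))
        assert np.array_equal(out.data, random_volume.data)

    def test_constant_shift_on_linear_ramp(self):
        n = 16
        ramp = Volume(np.indices((n, n), dtype=float)[0])
        out = warp_volume(ramp, constant_field((n, n), (2.0, 0.0)))
        # linear interpolation is exact on linear images (interior)
        np.testing.assert_allclose(
            out.data[: n - 3], ramp.data[: n - 3] + 2.0, atol=1e-12
        )

    def test_half_voxel_shift_matches_loop_oracle(self, rng):
        img = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)  # checkerboard
        D = constant_field((8, 8), (0.5, 0.0))
        out = warp_volume(Volume(img), D)
        np.testing.assert_allclose(out.data, loop_warp_2d(img, D.vectors), atol=1e-12)
        # averaging of adjacent checkerboard values gives 0.5 in the interior
        np.testing.assert_allclose(out.data[:7], 0.5, atol=1e-12)

    def test_random_field_matches_loop_oracle(self, rng, smooth_field_factory):
        img = rng.uniform(size=(12, 12))
        D = smooth_field_factory((12, 12), amplitude=2.5, smoothness=3)
        out = warp_volume(Volume(img), D)
        np.testing.assert_allclose(out.data, loop_warp_2d(img, D.vectors), atol=1e-12)

    def test_shape_mismatch_raises(self, random_volume):
        with pytest.raises(ValueError):
            warp_volume(random_volume, DisplacementField.zeros((5, 5)))


class TestWarpAndComposeFields:
    def test_warp_by_zero_leaves_field_unchanged(self, smooth_field_factory):
        D1 = smooth_field_factory()
        out = warp_field(D1, DisplacementField.zeros(D1.grid_shape))
        np.testing.assert_array_equal(out.vectors, D1.vectors)

    def test_constant_field_invariant_under_warping(self, smooth_field_factory):
        D1 = constant_field((16, 16), (1.5, -0.5))
        out = warp_field(D1, smooth_field_factory((16, 16)))
        np.testing.assert_allclose(out.vectors, D1.vectors, atol=1e-12)

    def test_warp_field_matches_componentwise_interpolation(
        self, rng, smooth_field_factory
    ):
        D1 = smooth_field_factory((12, 12), 2.0, 3.0)
        D2 = smooth_field_factory((12, 12), 1.5, 3.0)
        out = warp_field(D1, D2)
        for i in range(2):
            expected = loop_warp_2d(D1.vectors[..., i], D2.vectors)
            np.testing.assert_allclose(out.vectors[..., i], expected, atol=1e-12)

    def test_zero_is_neutral_for_composition(self, smooth_field_factory):
        D = smooth_field_factory()
        zero = DisplacementField.zeros(D.grid_shape)
        np.testing.assert_array_equal(compose_fields(D, zero).vectors, D.vectors)
        np.testing.assert_array_equal(compose_fields(zero, D).vectors, D.vectors)

    def test_translations_compose_additively(self):
        c1 = constant_field((10, 10), (0.5, 1.0))
        c2 = constant_field((10, 10), (-0.25, 2.0))
        out = compose_fields(c1, c2)
        np.testing.assert_allclose(
            out.vectors, c1.vectors + c2.vectors, atol=1e-12
        )

    def test_associativity_within_interpolation_tolerance(self, smooth_field_factory):
        fields = [smooth_field_factory((64, 64), 2.0, 12.0) for _ in range(3)]
        left = compose_fields(compose_fields(fields[0], fields[1]), fields[2])
        right = compose_fields(fields[0], compose_fields(fields[1], fields[2]))
        assert np.abs(left.vectors - right.vectors).max() <= 0.05

    def test_satisfies_defining_identity(self, smooth_field_factory):
        D1, D2 = smooth_field_factory(), smooth_field_factory()
        out = compose_fields(D1, D2)
        expected = D2.vectors + warp_field(D1, D2).vectors
        np.testing.assert_array_equal(out.vectors, expected)


def euler_flow_oracle(D, n_steps):
    """Tiny independent explicit-Euler integrator of du/dt = D(u)."""
    from scipy import ndimage

    nd = D.ndim
    u = np.indices(D.grid_shape, dtype=float).reshape(nd, -1)
    start = u.copy()
    for _ in range(n_steps):
        for i in range(nd):
            u[i] += (
                ndimage.map_coordinates(
                    D.vectors[..., i], u, order=1, mode="nearest"
                )
                / n_steps
            )
    out = (u - start).reshape((nd,) + D.grid_shape)
    return np.moveaxis(out, 0, -1)


class TestExpField:
    def test_exp_of_zero_is_identity(self):
        E = exp_field(DisplacementField.zeros((8, 8)))
        assert np.all(E.vectors == 0)

    def test_exp_of_constant_is_the_translation(self):
        c = constant_field((12, 12), (1.25, -2.0))
        E = exp_field(c)
        np.testing.assert_allclose(E.vectors, c.vectors, atol=1e-12)

    def test_linear_field_has_exponential_closed_form(self):
        # separable d0(x) = a x0 flows to x0 (e^a - 1) in the interior
        a = 0.05
        n = 33
        v = np.zeros((n, n, 2))
        v[..., 0] = a * np.indices((n, n), dtype=float)[0]
        E = exp_field(DisplacementField(v))
        x0 = np.indices((n, n), dtype=float)[0]
        expected = x0 * (np.exp(a) - 1.0)
        np.testing.assert_allclose(
            E.vectors[2:-6, :, 0], expected[2:-6, :], atol=0.02
        )

    def test_matches_fine_step_euler_integration(self, smooth_field_factory):
        D = smooth_field_factory((96, 96), amplitude=3.0, smoothness=24.0)
        E = exp_field(D)
        ref = euler_flow_oracle(D, 512)
        assert np.abs(E.vectors - ref).max() < 0.05

    def test_inverse_composes_to_identity(self, smooth_field_factory):
        D = smooth_field_factory((96, 96), amplitude=3.0, smoothness=24.0)
        comp = compose_fields(
            exp_field(DisplacementField(-D.vectors)), exp_field(D)
        )
        assert comp.max_norm() <= 0.1

    @pytest.mark.parametrize("alpha,beta", [(0.25, 0.25), (0.25, 0.5), (0.5, 0.5)])
    def test_semigroup_property(self, smooth_field_factory, alpha, beta):
        D = smooth_field_factory((96, 96), amplitude=4.0, smoothness=24.0)
        lhs = compose_fields(
            exp_field(DisplacementField(alpha * D.vectors)),
            exp_field(DisplacementField(beta * D.vectors)),
        )
        rhs = exp_field(DisplacementField((alpha + beta) * D.vectors))
        assert np.abs(lhs.vectors - rhs.vectors).max() <= 0.1

    def test_exponentials_never_fold(self, smooth_field_factory):
        for _ in range(20):
            D = smooth_field_factory((32, 32), amplitude=5.0, smoothness=6.0)
            assert jacobian_determinant(exp_field(D)).min() > 0


class TestJacobian:
    def test_zero_field_gives_unit_determinant(self):
        jac = jacobian_determinant(DisplacementField.zeros((6, 6, 6)))
        np.testing.assert_array_equal(jac.values, 1.0)

    @pytest.mark.parametrize("ndim,s", [(2, 1.1), (3, 0.9)])
    def test_uniform_scaling_gives_power_of_scale(self, ndim, s):
        n = 9
        shape = (n,) * ndim
        x = np.indices(shape, dtype=float)
        v = np.stack([(s - 1.0) * x[i] for i in range(ndim)], axis=-1)
        jac = jacobian_determinant(DisplacementField(v))
        interior = tuple([slice(1, -1)] * ndim)
        np.testing.assert_allclose(jac.values[interior], s ** ndim, atol=1e-12)

    def test_polynomial_field_matches_analytic_determinant(self):
        # d0 = a x0^2, d1 = b x0 x1: centered differences are exact on
        # quadratics, so interior determinants match the analytic formula
        a, b = 0.01, 0.02
        n = 12
        x0, x1 = np.indices((n, n), dtype=float)
        v = np.stack([a * x0 ** 2, b * x0 * x1], axis=-1)
        jac = jacobian_determinant(DisplacementField(v))
        expected = (1.0 + 2 * a * x0) * (1.0 + b * x0)
        np.testing.assert_allclose(jac.values[1:-1, 1:-1], expected[1:-1, 1:-1],
                                   atol=1e-10)

    def test_opposing_additive_fields_fold(self):
        # additive accumulation of two opposing deformations inverts voxels
        n = 17
        x0 = np.indices((n, n), dtype=float)[0] - (n - 1) / 2
        v = np.zeros((n, n, 2))
        v[..., 0] = -2.0 * x0  # d0 = -2 x0 -> J = 1 - 2 = -1
        jac = jacobian_determinant(DisplacementField(v))
        assert jac.min() < 0
        np.testing.assert_allclose(jac.values[1:-1, 1:-1], -1.0, atol=1e-12)

    def test_degenerate_grid_raises(self):
        with pytest.raises(ValueError):
            jacobian_determinant(DisplacementField.zeros((2, 5)))


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.floats(min_value=-1e3, max_value=1e3), min_size=36, max_size=36
    )
)
def test_warp_with_zero_field_is_identity_for_any_image(data):
    img = np.asarray(data).reshape(6, 6)
    vol = Volume(img)
    out = warp_volume(vol, DisplacementField.zeros((6, 6)))
    assert np.array_equal(out.data, img)


def test_volume_validation():
    with pytest.raises(ValueError):
        Volume(np.array([[np.nan, 1.0], [0.0, 2.0]]))
    with pytest.raises(ValueError):
        Volume(np.zeros((4, 4)), spacing=(1.0, -1.0))
    with pytest.raises(ValueError):
        DisplacementField(np.full((4, 4, 2), np.inf))
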