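"""Incomplete-Beta transform: oracle equivalence, curve shape, range mapping.

The independent oracle is adaptive quadrature of the defining integrals
(numerator and normalizing Beta integral), with the integrable endpoint
singularities handled by algebraic quadrature weights; it never calls the
implementation's special-function route.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from aquaenhance.beta_transform import (
    BetaParams,
    apply_beta,
    denormalize,
    incomplete_beta,
    normalize,
    transform_curve,
)
from aquaenhance.errors import (
    DegenerateInputError,
    DomainError,
    InvalidParameterError,
)
from aquaenhance.image import GrayImage


def _left_integral(a, b, hi):
    """∫₀^hi t^(a-1)(1-t)^(b-1) dt, t=0 singularity as a quadrature weight."""
    val, _ = integrate.quad(
        lambda t: (1.0 - t) ** (b - 1.0), 0.0, hi, weight="alg", wvar=(a - 1.0, 0.0)
    )
    return val


def quadrature_oracle(a, b, u):
    """Regularized incomplete Beta by direct quadrature of the integrals."""
    right, _ = integrate.quad(
        lambda t: t ** (a - 1.0), 0.5, 1.0, weight="alg", wvar=(0.0, b - 1.0)
    )
    total = _left_integral(a, b, 0.5) + right
    if u <= 0.0:
        return 0.0
    if u >= 1.0:
        return 1.0
    if u <= 0.5:
        num = _left_integral(a, b, u)
    else:
        mid, _ = integrate.quad(
            lambda t: t ** (a - 1.0) * (1.0 - t) ** (b - 1.0), 0.5, u
        )
        num = _left_integral(a, b, 0.5) + mid
    return num / total


class TestIncompleteBeta:
    @pytest.mark.parametrize("u", [0.0, 0.2, 0.5, 0.77, 1.0])
    def test_identity_when_both_shapes_are_one(self, u):
        assert incomplete_beta(BetaParams(1.0, 1.0), u) == pytest.approx(u, abs=1e-12)

    @pytest.mark.parametrize("a", [0.3, 1.0, 2.5, 9.9])
    def test_symmetric_shapes_fix_the_midpoint(self, a):
        assert incomplete_beta(BetaParams(a, a), 0.5) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("a,b", [(0.2, 7.0), (5.09, 9.97), (9.9, 0.3)])
    def test_endpoints_exact(self, a, b):
        params = BetaParams(a, b)
        assert incomplete_beta(params, 0.0) == 0.0
        assert incomplete_beta(params, 1.0) == 1.0

    def test_reference_optimum_matches_quadrature(self):
        # Shape pair selected for the reference tank image; value frozen from
        # the quadrature oracle above.
        value = incomplete_beta(BetaParams(5.09, 9.97), 0.338)
        assert value == pytest.approx(0.5237465564759581, abs=1e-6)
        assert value == pytest.approx(quadrature_oracle(5.09, 9.97, 0.338), abs=1e-6)

    def test_matches_quadrature_on_sampled_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            a, b = rng.uniform(0.1, 9.9, 2)
            u = rng.random()
            assert incomplete_beta(BetaParams(a, b), u) == pytest.approx(
                quadrature_oracle(a, b, u), abs=1e-6
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 9.9),
        b=st.floats(0.1, 9.9),
        u1=st.floats(0.0, 1.0),
        u2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_u(self, a, b, u1, u2):
        lo, hi = sorted((u1, u2))
        params = BetaParams(a, b)
        assert incomplete_beta(params, lo) <= incomplete_beta(params, hi) + 1e-12

    @pytest.mark.parametrize("u", [-0.1, 1.1])
    def test_u_outside_unit_interval_rejected(self, u):
        with pytest.raises(DomainError):
            incomplete_beta(BetaParams(2.0, 2.0), u)

    @pytest.mark.parametrize("a,b", [(0.0, 5.0), (10.0, 5.0), (5.0, -1.0), (5.0, 10.5)])
    def test_shape_parameters_outside_open_box_rejected(self, a, b):
        with pytest.raises(InvalidParameterError):
            BetaParams(a, b)

    def test_dark_stretching_vs_bright_stretching_taxonomy(self):
        u = np.linspace(0.05, 0.95, 19)
        dark_stretch = incomplete_beta(BetaParams(0.5, 2.0), u)
        bright_stretch = incomplete_beta(BetaParams(2.0, 0.5), u)
        assert np.all(dark_stretch > u)
        assert np.all(bright_stretch < u)


class TestTransformCurve:
    def test_identity_curve(self):
        pairs = transform_curve(BetaParams(1.0, 1.0), 11)
        for u, f in pairs:
            assert f == pytest.approx(u, abs=1e-12)

    @pytest.mark.parametrize("a,b", [(1.0, 1.0), (5.09, 9.97), (0.4, 0.7)])
    def test_endpoints_and_monotonicity(self, a, b):
        pairs = transform_curve(BetaParams(a, b), 51)
        assert pairs[0] == (0.0, 0.0)
        assert pairs[-1] == (1.0, 1.0)
        values = [f for _, f in pairs]
        assert all(v2 >= v1 for v1, v2 in zip(values, values[1:]))

    def test_s_curve_shape_for_reference_optimum(self):
        # Mid-stretching curve: gentle at both ends, steeper than the
        # identity near its steepest point.
        pairs = transform_curve(BetaParams(5.09, 9.97), 101)
        f = np.array([v for _, v in pairs])
        slopes = np.diff(f) * 100.0
        assert slopes[0] < 1.0
        assert slopes[-1] < 1.0
        assert slopes.max() > 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            transform_curve(BetaParams(2.0, 2.0), 1)


class TestRangeMapping:
    def test_normalize_three_level_example(self):
        image = GrayImage(np.array([[10.0, 60.0], [110.0, 60.0]]))
        out = normalize(image)
        assert np.array_equal(np.sort(np.unique(out.pixels)), [0.0, 0.5, 1.0])

    def test_normalize_hits_exact_endpoints(self, scene42):
        out = normalize(scene42[0])
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0

    def test_normalize_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize(GrayImage(np.full((4, 4), 77.0)))

    def test_denormalize_midpoint_and_quantization(self):
        unit = GrayImage(np.array([[0.0, 0.5], [1.0, 0.5]]), displayable=False)
        out = denormalize(unit, 8)
        assert out.pixels[0, 1] == 127.5
        assert out.quantized().pixels[0, 1] == 128.0
        assert out.pixels[0, 0] == 0.0
        assert out.pixels[1, 0] == 255.0

    def test_round_trip_is_identity_on_real_path(self):
        rng = np.random.default_rng(5)
        px = rng.random((16, 16))
        px[0, 0], px[0, 1] = 0.0, 1.0  # pin the range
        unit = GrayImage(px, displayable=False)
        back = normalize(denormalize(unit, 8))
        assert np.max(np.abs(back.pixels - px)) < 1e-12


class TestApplyBeta:
    def test_identity_params_leave_image_unchanged(self):
        rng = np.random.default_rng(9)
        unit = GrayImage(rng.random((8, 8)), displayable=False)
        out = apply_beta(unit, BetaParams(1.0, 1.0))
        assert np.max(np.abs(out.pixels - unit.pixels)) < 1e-12

    def test_endpoints_fixed_for_any_params(self):
        unit = GrayImage(np.array([[0.0, 1.0]]), displayable=False)
        out = apply_beta(unit, BetaParams(7.3, 0.4))
        assert np.array_equal(out.pixels, [[0.0, 1.0]])

    def test_lut_path_matches_exact_path(self, scene42):
        unit = normalize(scene42[0])
        params = BetaParams(5.09, 9.97)
        exact = apply_beta(unit, params, method="exact")
        lut = apply_beta(unit, params, method="lut")
        assert np.max(np.abs(exact.pixels - lut.pixels)) < 1e-6

    def test_pixels_outside_unit_interval_rejected(self):
        bad = GrayImage(np.array([[0.5, 1.2]]), displayable=False)
        with pytest.raises(DomainError):
            apply_beta(bad, BetaParams(2.0, 2.0))

    def test_rank_order_preserved_through_full_chain(self, scene42):
        image, _ = scene42
        unit = normalize(image)
        out = denormalize(apply_beta(unit, BetaParams(5.09, 9.97)), 8)
        a = image.pixels.ravel()
        b = out.pixels.ravel()
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order]) >= -1e-12)
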