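"""Distribution kernels: pointwise closed forms vs quadrature, weighting, matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from gpclust import (
    KernelSpec,
    MarginalCurve,
    GPKernelMatrix,
    gp_kernel,
    interval_weights,
    kernel_matrix,
    mixture_kernel,
    pointwise_kernel,
    resample_curve,
)
from conftest import make_curve, random_gaussian_pairs


def quad_kernel(mu1, v1, mu2, v2, family):
    """Adaptive quadrature of the defining integral — the independent oracle."""
    s1, s2 = np.sqrt(v1), np.sqrt(v2)
    integrands = {
        "BH": lambda z: np.sqrt(norm.pdf(z, mu1, s1) * norm.pdf(z, mu2, s2)),
        "EL": lambda z: norm.pdf(z, mu1, s1) * norm.pdf(z, mu2, s2),
        "OVL": lambda z: min(norm.pdf(z, mu1, s1), norm.pdf(z, mu2, s2)),
    }
    lo = min(mu1 - 12 * s1, mu2 - 12 * s2)
    hi = max(mu1 + 12 * s1, mu2 + 12 * s2)
    val, _ = quad(integrands[family], lo, hi, limit=400)
    return val


class TestIntervalWeights:
    def test_stated_example(self):
        w, span = interval_weights([0.0, 1.0, 2.0, 4.0])
        assert np.allclose(w, [0.5, 1.0, 1.5, 1.0])
        assert span == 4.0
        assert np.allclose(w / span, [0.125, 0.25, 0.375, 0.25])

    def test_uniform_grid_interior_weights(self):
        grid = np.arange(0, 3.1, 0.5)
        w, _ = interval_weights(grid)
        assert np.allclose(w[1:-1], 0.5)
        assert w[0] == w[-1] == 0.25

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2,
            max_size=40,
            unique=True,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weights_sum_to_span(self, points):
        grid = np.sort(np.asarray(points))
        if np.any(np.diff(grid) <= 1e-9):
            return
        w, span = interval_weights(grid)
        assert np.isclose(w.sum(), span, rtol=1e-12, atol=1e-12)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            interval_weights([1.0])


class TestPointwiseKernels:
    def test_bh_self_kernel_is_one(self):
        for mu, var in [(0.0, 1.0), (-3.2, 0.4), (7.0, 9.0)]:
            assert pointwise_kernel(mu, var, mu, var, "BH") == pytest.approx(1.0)

    def test_el_standard_normals(self):
        assert pointwise_kernel(0, 1, 0, 1, "EL") == pytest.approx(1 / np.sqrt(4 * np.pi))

    def test_ovl_unit_shift(self):
        # equal variances, single crossing
        assert pointwise_kernel(0, 1, 1, 1, "OVL") == pytest.approx(0.6171, abs=2e-4)

    def test_ovl_two_crossings_matches_quadrature(self):
        val = pointwise_kernel(0, 1, 0, 4, "OVL")
        assert val == pytest.approx(quad_kernel(0, 1, 0, 4, "OVL"), abs=1e-8)

    def test_sym_kl_zero_iff_identical(self):
        assert pointwise_kernel(0.5, 2.0, 0.5, 2.0, "KL") == 0.0
        assert pointwise_kernel(0.5, 2.0, 0.6, 2.0, "KL") > 0
        assert pointwise_kernel(0.5, 2.0, 0.5, 2.1, "KL") > 0

    @pytest.mark.parametrize("family", ["BH", "EL", "OVL"])
    def test_closed_forms_match_quadrature(self, family):
        mu1, v1, mu2, v2 = random_gaussian_pairs(60, seed=13)
        for args in zip(mu1, v1, mu2, v2):
            closed = pointwise_kernel(*args, family)
            assert closed == pytest.approx(quad_kernel(*args, family), abs=1e-7)

    def test_ovl_lower_bounds_bh(self):
        mu1, v1, mu2, v2 = random_gaussian_pairs(500, seed=17)
        ovl = pointwise_kernel(mu1, v1, mu2, v2, "OVL")
        bh = pointwise_kernel(mu1, v1, mu2, v2, "BH")
        assert np.all(ovl <= bh + 1e-12)

    def test_ovl_special_cases_are_continuous_limits(self):
        # equal-variance and identical branches agree with perturbed general case
        for eps in (1e-7, 1e-9):
            near = pointwise_kernel(0.3, 1.0, 1.1, 1.0 + eps, "OVL")
            exact = pointwise_kernel(0.3, 1.0, 1.1, 1.0, "OVL")
            assert near == pytest.approx(exact, abs=1e-5)
            near_id = pointwise_kernel(0.3, 1.0, 0.3 + eps, 1.0, "OVL")
            assert near_id == pytest.approx(1.0, abs=1e-5)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            pointwise_kernel(0, 0.0, 1, 1, "OVL")


class TestCurveKernels:
    def grid(self):
        return np.linspace(0, 10, 21)

    def test_identical_curves(self):
        g = self.grid()
        rng = np.random.default_rng(0)
        a = make_curve(g, rng.standard_normal(21), rng.uniform(0.1, 1, 21))
        assert gp_kernel(a, a, KernelSpec("OVL")) == pytest.approx(1.0)
        assert gp_kernel(a, a, KernelSpec("BH")) == pytest.approx(1.0)
        assert gp_kernel(a, a, KernelSpec("KL")) == pytest.approx(1.0)  # exp(0)

    def test_kl_self_kernel_is_exp_beta(self):
        g = self.grid()
        a = make_curve(g, np.sin(g), np.full(21, 0.3))
        spec = KernelSpec("KL", kl_beta=0.7)
        assert gp_kernel(a, a, spec) == pytest.approx(np.exp(0.7))

    def test_constant_pointwise_kernel_passes_through(self):
        # curves shifted by a constant: pointwise kernel constant in time
        for g in (np.linspace(0, 8, 9), np.sort(np.random.default_rng(1).uniform(0, 8, 15))):
            a = make_curve(g, np.zeros_like(g), np.ones_like(g))
            b = make_curve(g, np.ones_like(g), np.ones_like(g))
            kappa = pointwise_kernel(0.0, 1.0, 1.0, 1.0, "OVL")
            assert gp_kernel(a, b, KernelSpec("OVL")) == pytest.approx(kappa)

    def test_weighted_quadrature_oracle(self, curve_pair):
        a, b = curve_pair
        w, span = interval_weights(a.grid)
        expected = sum(
            wi * quad_kernel(m1, v1, m2, v2, "OVL")
            for wi, m1, v1, m2, v2 in zip(w, a.mean, a.var, b.mean, b.var)
        ) / span
        assert gp_kernel(a, b, KernelSpec("OVL")) == pytest.approx(expected, abs=1e-8)

    def test_symmetry(self, curve_pair):
        a, b = curve_pair
        for family in ("OVL", "BH", "EL", "KL"):
            spec = KernelSpec(family)
            assert gp_kernel(a, b, spec) == gp_kernel(b, a, spec)

    def test_grid_refinement_converges(self):
        # smooth curves: doubling resolution changes the kernel by < 1e-3
        for family in ("OVL", "BH", "EL", "KL"):
            spec = KernelSpec(family)
            vals = []
            for n in (41, 81):
                g = np.linspace(0, 10, n)
                a = make_curve(g, np.sin(g / 2), 0.3 + 0.1 * np.cos(g / 3))
                b = make_curve(g, 0.5 * np.cos(g / 2), 0.4 + 0.1 * np.sin(g / 4))
                vals.append(gp_kernel(a, b, spec))
            assert abs(vals[1] - vals[0]) < 1e-3

    def test_mismatched_grids_rejected(self):
        a = make_curve([0, 1, 2], [0, 0, 0], [1, 1, 1])
        b = make_curve([0, 1, 3], [0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            gp_kernel(a, b, KernelSpec("OVL"))

    def test_explicit_resampler(self):
        a = make_curve([0, 1, 2, 3], [0, 1, 2, 3], [1, 1, 1, 1])
        r = resample_curve(a, [0.5, 1.5, 2.5])
        assert np.allclose(r.mean, [0.5, 1.5, 2.5])


class TestMixtureKernel:
    def setup_method(self):
        g = np.linspace(0, 6, 13)
        rng = np.random.default_rng(9)
        self.curves = [
            make_curve(g, rng.standard_normal(13), rng.uniform(0.2, 1.0, 13))
            for _ in range(4)
        ]

    def test_ratio_endpoints(self):
        a, b, da, db = self.curves
        one = KernelSpec("OVL", mixture_ratio=1.0)
        zero = KernelSpec("OVL", mixture_ratio=0.0)
        assert mixture_kernel(a, b, da, db, one) == gp_kernel(a, b, one)
        assert mixture_kernel(a, b, da, db, zero) == gp_kernel(da, db, zero)

    def test_half_ratio_is_arithmetic_mean(self):
        a, b, da, db = self.curves
        spec = KernelSpec("BH", mixture_ratio=0.5)
        expected = 0.5 * gp_kernel(a, b, spec) + 0.5 * gp_kernel(da, db, spec)
        assert mixture_kernel(a, b, da, db, spec) == pytest.approx(expected)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("OVL", mixture_ratio=1.5)


class TestKernelMatrix:
    def test_identical_curves_give_all_ones(self):
        g = np.linspace(0, 5, 11)
        c = make_curve(g, np.sin(g), np.full(11, 0.2))
        km = kernel_matrix([c, c, c], KernelSpec("OVL"))
        assert np.allclose(km.values, 1.0)
        assert not km.psd_repaired

    def test_ovl_bounds_and_symmetry(self, curve_pair):
        a, b = curve_pair
        km = kernel_matrix([a, b], KernelSpec("OVL"))
        assert np.allclose(km.values, km.values.T)
        assert np.all(km.values >= 0) and np.all(km.values <= 1 + 1e-12)
        assert np.allclose(np.diag(km.values), 1.0)

    def test_kl_small_alpha_repair(self):
        # wildly different variances make the raw KL matrix indefinite
        rng = np.random.default_rng(2)
        g = np.linspace(0, 10, 11)
        curves = [
            make_curve(g, 3 * rng.standard_normal(11), rng.uniform(0.01, 5.0, 11))
            for _ in range(12)
        ]
        km = kernel_matrix(curves, KernelSpec("KL", kl_alpha=0.01))
        ev = np.linalg.eigvalsh(km.values)
        assert ev.min() >= -1e-8
        if km.psd_repaired:
            # repair only fires when the raw matrix was indefinite
            raw = kernel_matrix(curves[:2], KernelSpec("KL", kl_alpha=0.01))
            assert raw.values.shape == (2, 2)

    def test_mixture_matrix_matches_pairwise(self):
        g = np.linspace(0, 6, 13)
        rng = np.random.default_rng(8)
        vals = [make_curve(g, rng.standard_normal(13), rng.uniform(0.2, 1, 13)) for _ in range(3)]
        ders = [make_curve(g, rng.standard_normal(13), rng.uniform(0.2, 1, 13)) for _ in range(3)]
        spec = KernelSpec("OVL", mixture_ratio=0.3, use_derivatives=True)
        km = kernel_matrix(vals, spec, deriv_curves=ders)
        expected = mixture_kernel(vals[0], vals[1], ders[0], ders[1], spec)
        assert km.values[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_tsv_roundtrip(self, tmp_path, curve_pair):
        a, b = curve_pair
        km = kernel_matrix([a, b], KernelSpec("BH"), object_ids=["g1", "g2"])
        path = tmp_path / "k.tsv"
        km.to_tsv(path)
        back = GPKernelMatrix.from_tsv(path, spec=km.spec)
        assert back.object_ids == ["g1", "g2"]
        assert np.allclose(back.values, km.values)

    def test_spec_config_roundtrip(self):
        spec = KernelSpec("KL", kl_alpha=2.5, kl_beta=-0.1, mixture_ratio=0.7)
        assert KernelSpec.from_config(spec.to_config()) == spec
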