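"""Cartesian-Gaussian basis construction and weighted field contraction."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mifkit import (
    ApproxFunction,
    CGFBasis,
    CGFTerm,
    SigmoidWeight,
    alpha_from_rmax,
    build_basis,
    eval_cgf,
    evaluate,
    evaluate_lattice,
    fit,
    load_function,
    save_function,
)
from mifkit.cgfit import DEFAULT_RMAX, lattice_node_count
from mifkit.fixtures import default_field_spec, synthetic_field
from mifkit.molframe import SphericalGridSpec, make_spherical_grid


def random_basis(rng, n_terms, max_order=4):
    terms = []
    while len(terms) < n_terms:
        k, l = rng.integers(0, max_order + 1, 2)
        if k + l > max_order:
            continue
        m = int(rng.integers(0, max_order - k - l + 1))
        r = float(rng.uniform(1.5, 5.0))
        t = CGFTerm(int(k), int(l), m, alpha_from_rmax(int(k) + int(l) + m, r), r)
        if t not in terms:
            terms.append(t)
    return CGFBasis(tuple(terms))


class TestAlphaFromRmax:
    def test_radial_profile_peaks_at_rmax(self):
        """alpha = n/(2 r_max^2) puts the max of r^n exp(-a r^2) at r_max,
        confirmed by 1-D numeric maximization."""
        a = alpha_from_rmax(2, 3.0)
        assert a == pytest.approx(1.0 / 9.0, abs=1e-15)
        res = minimize_scalar(lambda r: -(r ** 2) * np.exp(-a * r * r),
                              bounds=(0.1, 10.0), method="bounded")
        assert abs(res.x - 3.0) < 1e-6

    def test_formula_identity(self):
        assert alpha_from_rmax(1, 1.0 / np.sqrt(2.0)) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_law(self):
        for n in range(1, 8):
            assert alpha_from_rmax(n, 6.0) == pytest.approx(alpha_from_rmax(n, 3.0) / 4)

    def test_s_type_reuses_p_scale(self):
        assert alpha_from_rmax(0, 2.5) == alpha_from_rmax(1, 2.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            alpha_from_rmax(2, -1.0)
        with pytest.raises(ValueError):
            alpha_from_rmax(8, 2.0)


class TestBuildBasis:
    def test_canonical_600_term_basis(self):
        basis = build_basis(7, DEFAULT_RMAX)
        assert len(basis) == 600
        assert basis.type_counts() == {
            "s": 5, "p": 15, "d": 30, "f": 50, "g": 75, "h": 105, "i": 140, "j": 180,
        }

    def test_small_enumerations(self):
        assert len(build_basis(1, [3.0])) == 4  # 1 s + 3 p
        assert len(build_basis(0, [2.0, 3.0, 4.0])) == 3

    def test_no_duplicate_shapes(self):
        basis = build_basis(3, [2.0, 4.0])
        keys = {(t.k, t.l, t.m, t.alpha) for t in basis}
        assert len(keys) == len(basis)

    def test_duplicate_rmax_rejected(self):
        with pytest.raises(ValueError):
            build_basis(2, [3.0, 3.0])


class TestEvalCGF:
    def test_s_term_at_origin_is_one(self):
        t = CGFTerm(0, 0, 0, alpha_from_rmax(0, 2.0), 2.0)
        assert eval_cgf(t, np.zeros(3)) == pytest.approx(1.0)

    def test_direct_substitution(self):
        t = CGFTerm(1, 0, 0, 0.25, np.sqrt(2.0))
        assert eval_cgf(t, np.array([2.0, 0, 0])) == pytest.approx(2 * np.exp(-1.0))

    def test_parity(self):
        """g(-r) = (-1)^(k+l+m) g(r) for 100 random terms and points."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            basis = random_basis(rng, 1)
            t = basis[0]
            p = rng.uniform(-4, 4, 3)
            assert eval_cgf(t, -p) == pytest.approx(
                (-1) ** t.order * eval_cgf(t, p), rel=1e-12, abs=1e-300)


class TestSigmoidWeight:
    def test_midpoint(self):
        w = SigmoidWeight()
        assert w(w.c) == pytest.approx((w.a + w.d) / 2)

    def test_zero_slope_limit(self):
        w = SigmoidWeight(b=0.0)
        e = np.linspace(0, 1, 11)
        assert np.allclose(w(e), (w.a + w.d) / 2)

    def test_monotone_and_positive_on_unit_interval(self):
        w = SigmoidWeight()
        e = np.linspace(0, 1, 101)
        vals = w(e)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) >= 0)
        assert w(1.0) > w(0.0)

    def test_nonpositive_configuration_rejected(self):
        with pytest.raises(ValueError):
            SigmoidWeight(a=-5.0, d=-1.0)


class TestFit:
    def _frame_points(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-6, 6, (n, 3))
        return pts

    def test_exact_representation_recovery(self):
        """A field synthesized as 0.7 g1 + 0.2 g2 is recovered exactly
        with uniform weights."""
        g1 = CGFTerm(0, 0, 0, alpha_from_rmax(0, 3.0), 3.0)
        g2 = CGFTerm(0, 0, 2, alpha_from_rmax(2, 3.6), 3.6)
        basis = CGFBasis((g1, g2))
        pts = self._frame_points()
        vals = 0.7 * np.asarray(eval_cgf(g1, pts)) + 0.2 * np.asarray(eval_cgf(g2, pts))
        fn, rep = fit((pts, vals), basis, weight=SigmoidWeight(a=1.0, b=0.0, d=1.0))
        assert np.allclose(fn.coefficients, [0.7, 0.2], atol=1e-8)
        assert rep.objective < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_pseudo_inverse_oracle(self, seed):
        """Normal-equation solve equals the independent brute-force
        weighted pseudo-inverse solution."""
        rng = np.random.default_rng(seed)
        basis = random_basis(rng, 20)
        pts = rng.uniform(-5, 5, (300, 3))
        vals = rng.uniform(0, 1, 300)
        w = rng.uniform(0.5, 5.0, 300)

        class W:
            def __call__(self, e):
                return w

        fn, rep = fit((pts, vals), basis, weight=W())
        G = basis.design_matrix(pts)
        sw = np.sqrt(w)
        oracle = np.linalg.pinv(sw[:, None] * G) @ (sw * vals)
        assert np.max(np.abs(fn.coefficients - oracle)) < 1e-8

    def test_ridge_limit_shrinks_coefficients(self):
        spec = default_field_spec()
        pts = self._frame_points(300, 1)
        vals = np.asarray(evaluate(spec.function(), pts))
        fn, _ = fit((pts, vals), CGFBasis(spec.terms), ridge=1e12)
        assert np.max(np.abs(fn.coefficients)) < 1e-6

    def test_objective_optimality(self):
        """Perturbing any recovered coefficient by +/-1e-3 never lowers
        the weighted objective."""
        rng = np.random.default_rng(4)
        basis = random_basis(rng, 6)
        pts = rng.uniform(-5, 5, (200, 3))
        vals = np.clip(rng.uniform(0, 1, 200), 0, 1)
        weight = SigmoidWeight()
        fn, rep = fit((pts, vals), basis, weight=weight)
        G = basis.design_matrix(pts)
        w = np.asarray(weight(vals))

        def delta(c):
            return float(np.sum(w * (vals - G @ c) ** 2))

        base = delta(fn.coefficients)
        assert base == pytest.approx(rep.objective, rel=1e-9, abs=1e-12)
        for i in range(len(basis)):
            for step in (1e-3, -1e-3):
                c = fn.coefficients.copy()
                c[i] += step
                assert delta(c) >= base - 1e-12

    def test_normal_matrix_symmetric(self):
        rng = np.random.default_rng(8)
        basis = random_basis(rng, 10)
        pts = rng.uniform(-5, 5, (100, 3))
        vals = rng.uniform(0, 1, 100)
        _, rep = fit((pts, vals), basis)
        assert np.max(np.abs(rep.A - rep.A.T)) < 1e-9

    def test_point_order_invariance(self):
        rng = np.random.default_rng(17)
        basis = random_basis(rng, 8)
        pts = rng.uniform(-5, 5, (150, 3))
        vals = rng.uniform(0, 1, 150)
        fn1, _ = fit((pts, vals), basis)
        perm = rng.permutation(150)
        fn2, _ = fit((pts[perm], vals[perm]), basis)
        assert np.max(np.abs(fn1.coefficients - fn2.coefficients)) < 1e-10

    def test_all_zero_weights_rejected(self):
        basis = CGFBasis((CGFTerm(0, 0, 0, alpha_from_rmax(0, 3.0), 3.0),))
        with pytest.raises(ValueError):
            fit((np.zeros((5, 3)), np.zeros(5)), basis, weight=lambda e: np.zeros(5))

    def test_non_finite_values_rejected(self):
        basis = CGFBasis((CGFTerm(0, 0, 0, alpha_from_rmax(0, 3.0), 3.0),))
        vals = np.array([0.1, np.nan, 0.3])
        with pytest.raises(ValueError):
            fit((np.zeros((3, 3)), vals), basis)

    def test_underdetermined_warns(self):
        rng = np.random.default_rng(3)
        basis = random_basis(rng, 10)
        with pytest.warns(UserWarning):
            fit((rng.uniform(-3, 3, (5, 3)), rng.uniform(0, 1, 5)), basis)

    def test_recovery_from_mif_field_object(self):
        """End-to-end: a synthetic field over the spherical scan grid is
        recovered with r^2 >= 0.999 when the basis contains the truth."""
        spec = default_field_spec()
        grid = make_spherical_grid(SphericalGridSpec(2.0, 7.0, 0.5, 30.0, 30.0))
        field = synthetic_field(spec, grid)
        fn, rep = fit(field, CGFBasis(spec.terms))
        assert rep.r_squared >= 0.999
        assert np.max(np.abs(fn.coefficients - spec.coefficients)) < 1e-6


class TestEvaluate:
    def test_single_s_term_at_origin(self):
        basis = CGFBasis((CGFTerm(0, 0, 0, alpha_from_rmax(0, 3.0), 3.0),))
        fn = ApproxFunction(basis, np.array([1.0]))
        assert evaluate(fn, np.zeros(3)) == pytest.approx(1.0)

    def test_canonical_lattice_node_count(self):
        assert lattice_node_count(0.1, 8.0) == 161 ** 3 == 4_173_281

    def test_small_lattice_geometry_and_values(self):
        spec = default_field_spec()
        fn = spec.function()
        grid = evaluate_lattice(fn, spacing=0.5, half_extent=2.0)
        assert grid.shape == (9, 9, 9)
        assert np.allclose(grid.origin, [-2.0] * 3)
        # center node is the origin
        assert grid.values[4, 4, 4] == pytest.approx(float(evaluate(fn, np.zeros(3))))

    def test_residuals_consistent_with_reported_objective(self):
        rng = np.random.default_rng(21)
        basis = random_basis(rng, 12)
        pts = rng.uniform(-5, 5, (200, 3))
        vals = rng.uniform(0, 1, 200)
        weight = SigmoidWeight()
        fn, rep = fit((pts, vals), basis, weight=weight)
        pred = np.asarray(evaluate(fn, pts))
        delta = float(np.sum(np.asarray(weight(vals)) * (vals - pred) ** 2))
        assert delta == pytest.approx(rep.objective, abs=1e-9)

    def test_clamped_view(self):
        basis = CGFBasis((CGFTerm(0, 0, 0, alpha_from_rmax(0, 3.0), 3.0),))
        fn = ApproxFunction(basis, np.array([5.0]))
        raw = evaluate(fn, np.zeros((1, 3)))
        clamped = evaluate(fn, np.zeros((1, 3)), clamp=True)
        assert raw[0] > 1.0 and clamped[0] == 1.0

    def test_invalid_spacing(self):
        fn = default_field_spec().function()
        with pytest.raises(ValueError):
            evaluate_lattice(fn, spacing=0.0)


class TestPersistence:
    def test_round_trip_600_terms(self, tmp_path):
        rng = np.random.default_rng(30)
        basis = build_basis(7, DEFAULT_RMAX)
        fn = ApproxFunction(basis, rng.normal(size=600))
        p = tmp_path / "fn.json"
        save_function(fn, p)
        back = load_function(p)
        pts = rng.uniform(-6, 6, (100, 3))
        assert np.max(np.abs(np.asarray(evaluate(fn, pts)) -
                             np.asarray(evaluate(back, pts)))) < 1e-12

    def test_empty_basis_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"terms": [], "coefficients": []}')
        with pytest.raises(ValueError):
            load_function(p)

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"terms": [{"k":0,"l":0,"m":0,"alpha":0.05555555555555555,'
                     '"r_max":3.0}], "coefficients": [1.0, 2.0]}')
        with pytest.raises(ValueError):
            load_function(p)
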