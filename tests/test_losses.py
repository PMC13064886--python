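"""Closed-form and oracle checks of every term of the composite loss."""

import numpy as np
import pytest

from vfpinn import losses as lo
from vfpinn.autodiff import value
from vfpinn.geometry import FREE_FACES, sample_collocation
from vfpinn.materials import isotropic_stiffness, voigt_to_full


@pytest.fixture
def interior(geom):
    return sample_collocation(geom, 2000, 50, 50, seed=17)


def _c_arrays(colloc, C):
    n = len(colloc.interior_points)
    return (
        np.broadcast_to(C, (n, 6, 6)).copy(),
        np.broadcast_to(voigt_to_full(C), (n, 3, 3, 3, 3)).copy(),
    )


class TestPdeResidual:
    def test_constant_field_zero_lambda_gives_zero(self, interior, polynomial_field_cls):
        fld = polynomial_field_cls(a=[0.3, -0.2, 0.5])
        u, _, H = fld.evaluate(interior.interior_points)
        C6, Cf = _c_arrays(interior, isotropic_stiffness(2e3, 0.3))
        assert lo.pde_residual_loss(u, H, Cf, 1030.0, 0.0) == pytest.approx(0.0)

    def test_constant_field_positive_lambda_closed_form(self, interior, polynomial_field_cls):
        """Stress divergence of a constant field vanishes, leaving only the
        inertial term: loss = lambda^2 rho^2 mean(u0^2)."""
        u0 = np.array([0.3, -0.2, 0.5])
        fld = polynomial_field_cls(a=u0)
        u, _, H = fld.evaluate(interior.interior_points)
        _, Cf = _c_arrays(interior, isotropic_stiffness(2e3, 0.3))
        lam, rho = 3.7e5, 1030.0
        got = lo.pde_residual_loss(u, H, Cf, rho, lam)
        assert got == pytest.approx(lam**2 * rho**2 * np.mean(u0**2), rel=1e-12)

    def test_polynomial_field_matches_finite_difference_divergence(
        self, geom, polynomial_field_cls
    ):
        """Residual of a smooth quadratic field at 20 points against an
        independent finite-difference evaluation of the stress divergence."""
        rng = np.random.default_rng(23)
        fld = polynomial_field_cls(
            a=rng.normal(size=3), B=rng.normal(size=(3, 3)),
            Q=rng.normal(size=(3, 3, 3)),
        )
        C = isotropic_stiffness(2e3, 0.25)
        Cf = voigt_to_full(C)
        lo_b, hi_b = geom.bounds
        pts = lo_b + (hi_b - lo_b) * (0.2 + 0.6 * rng.random((20, 3)))
        rho, lam = 1030.0, 2.5e5

        u, _, H = fld.evaluate(pts)
        div_sig = np.einsum("ijkl,pkjl->pi", Cf, H)
        resid = div_sig + rho * lam * u

        h = 1e-6

        def sigma(p):
            _, J, _ = fld.evaluate(p)
            eps = np.einsum("kij,pij->pk", lo.VOIGT_MAP, J)
            sv = eps @ C.T
            return np.einsum("kij,pk->pij", lo.VOIGT_MAP, sv)

        div_fd = np.zeros_like(u)
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = h
            div_fd += (sigma(pts + dx)[:, :, j] - sigma(pts - dx)[:, :, j]) / (2 * h)
        resid_fd = div_fd + rho * lam * u
        assert np.abs(resid - resid_fd).max() / np.abs(resid).max() < 1e-3

        # and the loss itself equals the mean squared residual
        got = lo.pde_residual_loss(u, H, np.broadcast_to(Cf, (20, 3, 3, 3, 3)).copy(),
                                   rho, lam)
        assert got == pytest.approx(np.mean(resid**2), rel=1e-12)


class TestRayleighQuotient:
    def test_scale_invariance_exact(self, interior, polynomial_field_cls):
        fld = polynomial_field_cls(B=np.diag([0.2, -0.4, 0.1]))
        u, J, _ = fld.evaluate(interior.interior_points)
        C6, _ = _c_arrays(interior, isotropic_stiffness(2e3, 0.3))
        w = interior.interior_weights
        r1 = lo.rayleigh_quotient(u, J, C6, 1030.0, w)
        r2 = lo.rayleigh_quotient(17.3 * u, 17.3 * J, C6, 1030.0, w)
        assert r2.value == pytest.approx(r1.value, rel=1e-14)
        assert r1.value > 0

    def test_zero_field_degenerate(self, interior, polynomial_field_cls):
        fld = polynomial_field_cls()
        u, J, _ = fld.evaluate(interior.interior_points)
        C6, _ = _c_arrays(interior, isotropic_stiffness(2e3, 0.3))
        with pytest.raises(lo.DegenerateFieldError):
            lo.rayleigh_quotient(u, J, C6, 1030.0, interior.interior_weights)

    def test_uniform_shear_closed_form(self, interior, geom):
        """u = (0, 0, g x): only AP shear strain; lambda = G g^2 V /
        (rho g^2 integral x^2) — both integrals known in closed form."""
        g = 2.0
        pts = interior.interior_points
        u = np.zeros_like(pts)
        u[:, 2] = g * pts[:, 0]
        J = np.zeros((len(pts), 3, 3))
        J[:, 2, 0] = g
        Ciso = isotropic_stiffness(2e3, 0.0)  # G = E/2
        C6, _ = _c_arrays(interior, Ciso)
        r = lo.rayleigh_quotient(u, J, C6, 1030.0, interior.interior_weights)
        G = 1e3
        # V = G g^2 Vol ; T = rho g^2 int x^2 dV = rho g^2 Vol D^2/3
        lam_exact = G / (1030.0 * geom.depth**2 / 3.0)
        # quadrature error only in T (x^2 not integrated exactly)
        assert r.value == pytest.approx(lam_exact, rel=0.05)


class TestBoundaryLosses:
    def test_zero_field_all_zero(self, interior, polynomial_field_cls):
        fld = polynomial_field_cls()
        free = interior.surface_mask(FREE_FACES)
        u, J, _ = fld.evaluate(interior.surface_points[free])
        n = interior.surface_normals[free]
        C6 = np.broadcast_to(isotropic_stiffness(2e3, 0.3), (len(u), 6, 6)).copy()
        assert lo.dirichlet_loss(u) == pytest.approx(0.0)
        assert lo.neumann_loss(J, C6, n) == pytest.approx(0.0)

    def test_uniform_translation_closed_form(self, interior):
        """Constant field: dirichlet = |u0|^2, zero stress so neumann and
        interface vanish."""
        u0 = np.array([0.1, -0.7, 0.4])
        free = interior.surface_mask(FREE_FACES)
        nf = int(free.sum())
        u = np.broadcast_to(u0, (nf, 3)).copy()
        J = np.zeros((nf, 3, 3))
        C6 = np.broadcast_to(isotropic_stiffness(2e3, 0.3), (nf, 6, 6)).copy()
        assert lo.dirichlet_loss(u) == pytest.approx(np.sum(u0**2), rel=1e-12)
        assert lo.neumann_loss(J, C6, interior.surface_normals[free]) == 0.0
        ni = len(interior.interface_points)
        ui = np.broadcast_to(u0, (ni, 3)).copy()
        Ji = np.zeros((ni, 3, 3))
        C6i = np.broadcast_to(isotropic_stiffness(2e3, 0.3), (ni, 6, 6)).copy()
        got = lo.interface_loss(ui, ui, Ji, Ji, C6i, C6i, np.array([1.0, 0, 0]))
        assert value(got) == pytest.approx(0.0)

    def test_linear_field_neumann_matches_hand_computed_traction(self, interior):
        """u = A x with isotropic C: sigma is constant; |sigma n|^2 per face
        is hand-computable."""
        A = np.array([[0.2, 0.1, 0.0], [0.0, -0.3, 0.05], [0.1, 0.0, 0.2]])
        C = isotropic_stiffness(2e3, 0.25)
        eps = 0.5 * (A + A.T)
        eps_v = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                          2 * eps[1, 2], 2 * eps[0, 2], 2 * eps[0, 1]])
        sv = C @ eps_v
        sigma = np.array([[sv[0], sv[5], sv[4]],
                          [sv[5], sv[1], sv[3]],
                          [sv[4], sv[3], sv[2]]])
        free = interior.surface_mask(FREE_FACES)
        pts = interior.surface_points[free]
        normals = interior.surface_normals[free]
        u = pts @ A.T
        J = np.broadcast_to(A, (len(pts), 3, 3)).copy()
        C6 = np.broadcast_to(C, (len(pts), 6, 6)).copy()
        expected = np.mean(np.sum((normals @ sigma.T) ** 2, axis=1))
        got = lo.neumann_loss(J, C6, normals)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_interface_jump_detects_mismatched_stiffness(self, interior):
        """A pure AP-shear field across the interface produces a traction jump
        proportional to the GAP difference, and no displacement jump."""
        from vfpinn.materials import build_layer_elasticity

        ni = len(interior.interface_points)
        pts = interior.interface_points
        u = np.zeros((ni, 3)); u[:, 2] = 0.1 * pts[:, 0]
        J = np.zeros((ni, 3, 3)); J[:, 2, 0] = 0.1
        Cc = build_layer_elasticity(2e3, 10e3).C_voigt
        Cb = build_layer_elasticity(2e3, 20e3).C_voigt
        C6c = np.broadcast_to(Cc, (ni, 6, 6)).copy()
        C6b = np.broadcast_to(Cb, (ni, 6, 6)).copy()
        got = value(lo.interface_loss(u, u, J, J, C6c, C6b, np.array([1.0, 0, 0])))
        # traction jump = (GAP_b - GAP_c) * du3/dx on the 3-component
        expected = ((20e3 - 10e3) * 0.1) ** 2
        assert got == pytest.approx(expected, rel=1e-12)


class TestDataLosses:
    @pytest.mark.parametrize(
        "ratio,expected", [(1.0, 0.0), (2.0, 1.0), (0.0, 1.0)]
    )
    def test_eigenvalue_loss_plug_ins(self, ratio, expected):
        assert value(lo.eigenvalue_loss(ratio * 4.2e5, 4.2e5)) == pytest.approx(expected)

    def test_eigenvalue_loss_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            lo.eigenvalue_loss(1.0, 0.0)

    def test_cosine_loss_aligned_opposed_orthogonal(self):
        rng = np.random.default_rng(31)
        u = rng.normal(size=(40, 3))
        assert value(lo.cosine_loss(u, u)) == pytest.approx(0.0)
        assert value(lo.cosine_loss(u, -u)) == pytest.approx(2.0)
        rot = u[:, :2] @ np.array([[0.0, 1.0], [-1.0, 0.0]])  # pointwise orthogonal
        assert value(lo.cosine_loss(u[:, :2], rot)) == pytest.approx(1.0)

    def test_cosine_loss_zero_norm_degenerate(self):
        with pytest.raises(lo.DegenerateFieldError):
            lo.cosine_loss(np.zeros((5, 3)), np.ones((5, 3)))


class TestTotalLoss:
    def test_unit_weights_sum_terms_exactly(self):
        terms = dict(zip(lo.LOSS_TERMS, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]))
        total, bd = lo.total_loss(terms)
        assert value(total) == pytest.approx(sum(terms.values()), rel=1e-15)
        assert bd.total == pytest.approx(2.1)

    def test_doubling_one_weight_adds_that_term(self):
        terms = dict(zip(lo.LOSS_TERMS, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]))
        t1, _ = lo.total_loss(terms)
        t2, _ = lo.total_loss(terms, {"neumann": 2.0})
        assert value(t2) - value(t1) == pytest.approx(terms["neumann"], rel=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            lo.total_loss({"pde": 1.0}, {"pde": -0.5})

    def test_all_zero_terms_zero_total(self):
        total, bd = lo.total_loss({})
        assert value(total) == 0.0
        assert bd.cosine == 0.0
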