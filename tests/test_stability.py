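"""Linearization, adjoint solvability and the transverse coefficient."""

import numpy as np
import pytest

from acidfront.model_core import ModelParams, dispersion_matrix
from acidfront.stability import (
    adjoint_null,
    assemble_linearization,
    default_ell_max,
    fit_lambda_c2,
    lambda_c2,
    lambda_c2_asymptotic,
    lambda_curve,
    spectrum,
)
from acidfront.traveling_wave import end_equilibria, solve_front


class TestLinearization:
    def test_front_derivative_is_near_null_at_ell_zero(self, fig1_front):
        # cancellation metric: ||A phi'|| against ||(|A| |phi'|)||, which
        # normalizes out the O(1/(eps h)^2) operator entries
        op = assemble_linearization(fig1_front, 0.0)
        phi = op.pack(op.deriv)
        res = np.linalg.norm(op.A @ phi)
        den = np.linalg.norm(np.abs(op.A) @ np.abs(phi))
        assert res / den < 1e-8

    def test_transverse_terms_enter_as_diagonal_weights(self, fig1_front):
        # A(l) - A(0) must equal -l^2 * diag(0, 1+k-u_h, 1/eps^2) exactly
        ell = 0.37
        A0 = assemble_linearization(fig1_front, 0.0)
        Al = assemble_linearization(fig1_front, ell)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(A0.A.shape[0])
        diff = A0.A @ x - Al.A @ x
        expect = ell**2 * A0.pack(A0.M * A0.unpack(x))
        # atol set by float cancellation of the O(1/(eps h)^2) entries
        np.testing.assert_allclose(
            diff, expect, atol=1e-10 * np.max(np.abs(A0.A @ x))
        )

    def test_end_state_essential_spectrum_in_left_half_plane(self, fig8_fronts):
        # dispersion relations of the end equilibria (comoving symbol
        # J - k^2 D - i k c) stay strictly left of the imaginary axis
        ks = np.concatenate([np.linspace(0, 2, 40), np.geomspace(2, 200, 30)])
        for tw in fig8_fronts.values():
            left, right, _ = end_equilibria(tw.params, tw.c,
                                            tw.singular.regime.kind)
            for eq in (left, right):
                UVW = eq[[0, 1, 3]]
                for k in ks:
                    Ak = dispersion_matrix(UVW, k, tw.params) \
                        - 1j * k * tw.c * np.eye(3)
                    assert np.max(np.linalg.eigvals(Ak).real) < -1e-4


class TestSpectrum:
    def test_translational_mode_flagged(self, fig1_front):
        lam, vecs, flags, _ = spectrum(fig1_front, 0.0, count=12, shift=1e-8)
        assert flags.sum() == 1
        assert abs(lam[np.argmax(flags)]) < 1e-5

    def test_symmetric_in_ell(self, fig1_front):
        # only |l| enters the operator, so the discretizations at +-l are
        # identical matrices (spectra coincide exactly, not just nearly)
        Ap = assemble_linearization(fig1_front, 0.02).A
        Am = assemble_linearization(fig1_front, -0.02).A
        assert abs(Ap - Am).max() == 0.0


class TestAdjoint:
    def test_discrete_fredholm_orthogonality(self, fig1_front):
        adj = adjoint_null(fig1_front)
        op = adj.op
        phi = op.pack(op.deriv)
        # <L phi', psi> with the discrete left null vector: exact to solver
        # accuracy by the transpose construction
        assert abs(adj.y @ (op.A @ phi)) < 1e-6 * np.linalg.norm(phi)

    def test_normalized_denominator(self, fig1_front):
        adj = adjoint_null(fig1_front)
        assert adj.y @ adj.op.pack(adj.op.deriv) == pytest.approx(1.0, rel=1e-10)

    def test_analytic_adjoint_residual(self, fig1_front):
        # cross-check against the printed adjoint operator.  The tumor row
        # is checked pointwise on a mollified copy of the adjoint (the
        # discrete-transpose null vector carries harmless mesh-scale
        # noise); the normal-cell and acid rows are singularly perturbed
        # (derivative scales c/|F_u| and eps), so they are checked through
        # their integrated identities, in which the derivative terms drop.
        from scipy.ndimage import gaussian_filter1d

        adj = adjoint_null(fig1_front)
        tw = fig1_front
        p, c = tw.params, tw.c

        # v-row, pointwise: D vA'' + (c - u_h') vA' + Gv vA + Hv wA = 0
        xi = np.arange(-25.0, 25.0, 0.02)
        prof = tw.interpolant()(xi)
        u_h, v_h, w_h = prof[0], prof[1], prof[3]
        Gv = p.rho * (-3 * v_h**2 + 2 * (1 + p.a) * v_h - p.a) - p.delta2 * w_h
        Duu = 1 + p.kappa - u_h
        du_h = np.gradient(u_h, xi)
        sm = lambda g: gaussian_filter1d(np.interp(xi, adj.xi, g), 12.5)
        vA, wA = sm(adj.v_A), sm(adj.w_A)
        d = lambda g: np.gradient(g, xi)
        terms = [Duu * d(d(vA)), (c - du_h) * d(vA), Gv * vA, p.delta3 * wA]
        sl = slice(100, -100)
        scale = max(np.max(np.abs(t[sl])) for t in terms)
        assert np.max(np.abs(sum(terms)[sl])) < 5e-2 * scale

        # u-row, weak: int(Fu uA + v_h' vA') = 0 since c uA' integrates out
        from acidfront.stability import front_derivatives

        w_q = adj.op.quad_w
        uh, vh, wh = tw.u[1:-1], tw.v[1:-1], tw.w[1:-1]
        dv = front_derivatives(tw)[1][1:-1]
        Fu = 1 - 2 * uh - p.delta1 * wh
        dvA = np.gradient(adj.v_A, adj.xi)
        I1 = np.sum(w_q * (Fu * adj.u_A + dv * dvA))
        S1 = np.sum(w_q * (np.abs(Fu * adj.u_A) + np.abs(dv * dvA)))
        assert abs(I1) / S1 < 5e-3

        # w-row, weak: int(Fw uA + Gw vA - d3 wA) = 0
        Fw, Gw = -p.delta1 * uh, -p.delta2 * vh
        I3 = np.sum(w_q * (Fw * adj.u_A + Gw * adj.v_A - p.delta3 * adj.w_A))
        S3 = np.sum(w_q * (np.abs(Fw * adj.u_A) + np.abs(Gw * adj.v_A)
                           + p.delta3 * np.abs(adj.w_A)))
        assert abs(I3) / S3 < 1e-5

    def test_fast_field_adjoint_shape(self, fig1_front):
        # in the fast field the tumor adjoint component follows
        # v_h,xi * exp(-c xi / (1+kappa-u_h)) up to a constant factor
        adj = adjoint_null(fig1_front)
        tw = fig1_front
        p = tw.params
        m = (adj.xi > -3) & (adj.xi < 3)
        from acidfront.stability import front_derivatives

        dv = front_derivatives(tw)[1][1:-1]
        D = 1 + p.kappa - tw.u[1:-1]
        ref = dv[m] * np.exp(-tw.c * adj.xi[m] / D[m])
        ratio = adj.v_A[m] / ref
        assert np.std(ratio) / abs(np.mean(ratio)) < 0.05


class TestLambdaC2:
    def test_quotient_invariant_under_adjoint_rescaling(self, fig1_front):
        adj = adjoint_null(fig1_front)
        lc2 = lambda_c2(fig1_front, adj)
        adj.y *= 7.3
        assert lambda_c2(fig1_front, adj) == pytest.approx(lc2, rel=1e-12)

    def test_gap_presets_unstable(self, fig8_fronts):
        for name, tw in fig8_fronts.items():
            assert lambda_c2(tw) > 0, name

    def test_benign_weak_toxicity_stable(self, benign_front):
        assert lambda_c2(benign_front) < 0

    def test_sign_agreement_with_asymptotics(self, fig8_fronts, benign_front):
        for tw in list(fig8_fronts.values()) + [benign_front]:
            lc2 = lambda_c2(tw)
            _, sign = lambda_c2_asymptotic(tw.params)
            assert np.sign(lc2) == sign

    def test_gap_with_no_tumor_toxicity_is_neutral(self):
        # in the gap case u* = 0; with delta2 = 0 as well, the sign integral
        # vanishes identically at leading order
        p = ModelParams(a=0.1, kappa=0.1, delta1=4.0, delta2=0.0,
                        delta3=70.0, rho=1.0, eps=0.01)
        val, sign = lambda_c2_asymptotic(p)
        assert val == pytest.approx(0.0, abs=1e-12)
        assert sign == 0.0


class TestLambdaCurve:
    def test_datum_and_quadratic_regime(self, fig1_front):
        lc2 = lambda_c2(fig1_front)
        crv = lambda_curve(fig1_front, 0.25 * default_ell_max(fig1_front),
                           n_points=7)
        assert crv[0, 1] == 0.0
        fit = np.polyfit(crv[:, 0] ** 2, crv[:, 1], 1)
        resid = crv[:, 1] - np.polyval(fit, crv[:, 0] ** 2)
        ss_tot = np.sum((crv[:, 1] - crv[:, 1].mean()) ** 2)
        assert 1 - np.sum(resid**2) / ss_tot > 0.999
        assert fit_lambda_c2(crv) == pytest.approx(lc2, rel=0.05)

    def test_unstable_branch_rises_then_falls(self, row4_front):
        crv = lambda_curve(row4_front, 0.3, n_points=12)
        lam = crv[1:, 1]
        imax = np.argmax(lam)
        assert lam[imax] > 0
        assert 0 < imax < len(lam) - 1
        assert lam[-1] < lam[imax]
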