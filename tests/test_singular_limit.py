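"""Layer fronts, slow Hamiltonian orbits and the singular concatenation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from acidfront.model_core import ModelParams, RegimeKind, equilibrium_V
from acidfront.singular_limit import (
    FoldError,
    fold_bound,
    gap_boundary_delta1,
    hamiltonian,
    layer_front,
    layer_speed,
    singular_front,
    slow_orbit,
    slow_p_plus,
    solve_w_star,
    v_branch,
)

from conftest import random_params, shooting_layer_speed


def mp(**kw):
    base = dict(a=0.1, kappa=0.1, delta1=4.0, delta2=0.1, delta3=70.0,
                rho=1.0, eps=0.01)
    base.update(kw)
    return ModelParams(**base)


class TestVBranch:
    def test_at_zero_acid(self):
        p = mp(a=0.3)
        assert v_branch(0.0, p) == pytest.approx((1.0, 0.3))

    def test_fold_collision(self):
        p = mp(a=0.2, delta2=0.5, delta1=1.0)
        wf = fold_bound(p)
        vp, vm = v_branch(wf, p)
        assert vp == pytest.approx(vm) == pytest.approx((1 + p.a) / 2)

    def test_delta2_zero_independent_of_w(self):
        p = mp(delta2=0.0)
        assert v_branch(5.0, p) == pytest.approx((1.0, 0.1))

    def test_beyond_fold_raises(self):
        p = mp(a=0.2, delta2=0.5, delta1=1.0)
        with pytest.raises(FoldError, match="outside"):
            v_branch(fold_bound(p) * 1.01, p)


class TestLayerFront:
    def test_profile_satisfies_planar_ode(self):
        # substitute (v, q)(xi) into the layer ODE and bound the residual
        rng = np.random.default_rng(2)
        xi = np.linspace(-30, 30, 2001)
        for _ in range(10):
            p = random_params(rng)
            w = rng.uniform(0, min(1 / p.delta1, fold_bound(p), 0.9))
            br = int(rng.integers(0, 2))
            lf = layer_front(w, br, p)
            v, q = lf.v(xi), lf.q(xi)
            res_v = np.gradient(v, xi) - (q + lf.speed * v) / lf.diffusion
            res_q = lf.q_xi(xi) - (
                -p.rho * v * (1 - v) * (v - p.a) + p.delta2 * v * w
            )
            # gradient() is second order; compare q' analytically instead
            assert np.max(np.abs(res_q)) < 1e-8
            assert np.max(np.abs(res_v)) < 1e-3  # FD-limited check of v'

    def test_centering_and_limits(self):
        lf = layer_front(0.1, 1, mp())
        assert lf.v(0.0) == pytest.approx(lf.v_plus_at_w / 2)
        assert lf.v(-60.0) == pytest.approx(0.0, abs=1e-12)
        assert lf.v(60.0) == pytest.approx(lf.v_plus_at_w, abs=1e-12)

    def test_speed_example(self):
        # shooting-verified value for branch 1 at w = 0, (a,kappa,rho)=(0.1,0.1,1)
        p = mp(delta2=0.0, delta1=1.0)
        assert layer_speed(0.0, 1, p) == pytest.approx(0.17889, abs=5e-6)

    def test_speed_zero_at_balanced_allee(self):
        p = mp(a=0.5, delta2=0.0, delta1=1.0)
        assert layer_speed(0.0, 0, p) == pytest.approx(0.0, abs=1e-14)
        assert layer_speed(0.0, 1, p) == pytest.approx(0.0, abs=1e-14)

    def test_speed_matches_shooting(self):
        rng = np.random.default_rng(4)
        for _ in range(6):
            p = random_params(rng)
            w = rng.uniform(0, min(1 / p.delta1, fold_bound(p), 0.9))
            br = int(rng.integers(0, 2))
            assert layer_speed(w, br, p) == pytest.approx(
                shooting_layer_speed(w, br, p), abs=1e-6
            )

    def test_branch1_requires_subtranscritical_w(self):
        with pytest.raises(ValueError, match="branch 1"):
            layer_front(0.5, 1, mp(delta1=4.0))


class TestHamiltonian:
    def test_anchor_values(self):
        p = mp()
        Vp = equilibrium_V(p)[0]
        assert hamiltonian(0.0, 0.0, "M0", p) == 0.0
        assert hamiltonian(Vp, 0.0, "Mplus", p) == pytest.approx(0.0, abs=1e-12)

    def test_delta2_zero_closed_form(self):
        p = mp(delta2=0.0)
        d3 = p.delta3
        for w, pp in ((0.3, 1.0), (0.7, -2.0)):
            expect = pp**2 / 2 - d3 * w**2 / 2 + d3 / 2 + d3 * (w - 1)
            assert hamiltonian(w, pp, "Mplus", p) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("branch", ["M0", "Mplus"])
    def test_conserved_along_integrated_orbit(self, branch):
        # independent RK integration of the reduced flow: E drift < 1e-9
        p = mp()
        w_star, p_star = solve_w_star(p)
        d3 = p.delta3

        def rhs(z, y):
            w, q = y
            v = 0.0 if branch == "M0" else v_branch(w, p)[0]
            return [q, d3 * (w - v)]

        y0 = [w_star, p_star]
        span = (0.0, -0.3) if branch == "M0" else (0.0, 0.3)
        sol = solve_ivp(rhs, span, y0, rtol=1e-12, atol=1e-14, dense_output=True)
        zs = np.linspace(*span, 50)
        E = [hamiltonian(w, q, branch, p) for w, q in sol.sol(zs).T]
        assert np.max(np.abs(np.array(E) - E[0])) < 1e-9


class TestWStar:
    def test_delta2_zero_exact_half(self):
        for a, rho in ((0.1, 1.0), (0.35, 3.0)):
            w, p_ = solve_w_star(mp(a=a, rho=rho, delta2=0.0))
            assert w == pytest.approx(0.5, abs=1e-13)

    def test_energy_matching_definition(self):
        p = mp(a=0.35, rho=1.0, delta2=0.1, delta1=12.5)
        w_star, p_star = solve_w_star(p)
        assert hamiltonian(w_star, p_star, "Mplus", p) == pytest.approx(0.0, abs=1e-10)
        assert p.delta1 * w_star > 1  # gap case per the regime map

    def test_monotone_nonincreasing_in_delta2(self):
        ws = [solve_w_star(mp(a=0.1, rho=1.0, delta2=d2))[0]
              for d2 in np.linspace(0.0, 0.3, 7)]
        assert all(b <= a + 1e-12 for a, b in zip(ws, ws[1:]))


class TestSlowOrbit:
    def test_m0_exponential(self):
        p = mp()
        w_star, _ = solve_w_star(p)
        orb = slow_orbit("M0", p, w_star)
        assert orb.w[-1] == pytest.approx(w_star)
        np.testing.assert_allclose(orb.p / orb.w, np.sqrt(p.delta3), rtol=1e-12)

    def test_mplus_energy_and_endpoint(self):
        p = mp()
        w_star, _ = solve_w_star(p)
        orb = slow_orbit("Mplus", p, w_star)
        E = [hamiltonian(w, q, "Mplus", p) for w, q in zip(orb.w, orb.p)]
        assert np.max(np.abs(E)) < 1e-9
        Vp = equilibrium_V(p)[0]
        assert abs(orb.w[-1] - Vp) < 2e-6 and abs(orb.p[-1]) < 1e-4

    def test_p_plus_closed_form_matches_orbit(self):
        p = mp()
        w_star, _ = solve_w_star(p)
        orb = slow_orbit("Mplus", p, w_star)
        mid = len(orb.w) // 2
        assert slow_p_plus(orb.w[mid], p) == pytest.approx(orb.p[mid], rel=1e-8)


class TestSingularFront:
    def test_benign_segments(self):
        sf = singular_front(mp(delta2=0.0, delta1=0.5))
        assert [s[0] for s in sf.segments] == [
            "slow_M0_1", "jump", "slow_Mplus_1"]
        assert sf.jump_branch == 1 and sf.gap_width_zeta == 0.0

    def test_no_gap_segments(self):
        sf = singular_front(mp(delta2=0.0, delta1=1.5))
        assert [s[0] for s in sf.segments] == [
            "slow_M0_1", "jump", "slow_Mplus_1", "slow_Mplus_0"]

    def test_gap_segments_and_width(self):
        sf = singular_front(mp(delta2=0.0, delta1=4.0, delta3=70.0))
        assert [s[0] for s in sf.segments] == [
            "slow_M0_1", "slow_M0_0", "jump", "slow_Mplus_0"]
        assert sf.jump_branch == 0
        assert sf.gap_width_zeta == pytest.approx(np.log(2) / np.sqrt(70), rel=1e-12)

    def test_gap_speed_uses_acid_only_branch(self):
        p = mp(delta2=0.0, delta1=4.0)
        sf = singular_front(p)
        # with delta2 = 0: v±(w*) = (1, a), so c0 = sqrt(2 rho (1+kappa)) (1/2 - a)
        expect = np.sqrt(2 * p.rho * (1 + p.kappa)) * (0.5 - p.a)
        assert sf.c_star == pytest.approx(expect, rel=1e-12)

    def test_gap_width_equals_time_of_flight(self):
        # oracle: integrate the acid-only reduced flow from w = 1/delta1 to
        # w* and compare the elapsed slow time with the closed form
        p = mp(a=0.2, rho=1.3, delta2=0.15, delta1=5.0, delta3=30.0)
        sf = singular_front(p)
        assert sf.regime.kind is RegimeKind.MALIGNANT_GAP
        d3 = p.delta3

        def rhs(z, y):
            return [y[1], d3 * y[0]]

        def hit(z, y):
            return y[0] - sf.w_star

        hit.terminal = True
        w0 = 1.0 / p.delta1
        sol = solve_ivp(rhs, (0, 10), [w0, np.sqrt(d3) * w0], events=hit,
                        rtol=1e-13, atol=1e-15)
        assert sol.t_events[0][0] == pytest.approx(sf.gap_width_zeta, abs=1e-8)


class TestGapBoundary:
    def test_delta2_zero(self):
        assert gap_boundary_delta1(mp(delta2=0.0)) == pytest.approx(2.0, abs=1e-10)

    def test_inverse_of_w_star(self):
        p = mp(a=0.3, delta2=0.2, rho=2.0)
        assert gap_boundary_delta1(p) == pytest.approx(1.0 / solve_w_star(p)[0])

    def test_regime_flips_across_boundary(self):
        from acidfront.model_core import classify_regime

        p = mp(a=0.3, delta2=0.2, rho=2.0)
        d1c = gap_boundary_delta1(p)
        lo = classify_regime(p.with_(delta1=d1c - 1e-6))
        hi = classify_regime(p.with_(delta1=d1c + 1e-6))
        assert lo.kind is RegimeKind.MALIGNANT_NO_GAP
        assert hi.kind is RegimeKind.MALIGNANT_GAP
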