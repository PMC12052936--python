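import numpy as np
import pytest

from acidfront.model_core import ModelParams
from acidfront.traveling_wave import solve_front
from acidfront.workbench import load_preset


@pytest.fixture(scope="session")
def fig1_params() -> ModelParams:
    return load_preset("fig1").params


@pytest.fixture(scope="session")
def fig1_front(fig1_params):
    """Converged Fig-1 front, shared across the suite (expensive)."""
    return solve_front(fig1_params, tol=1e-8)


@pytest.fixture(scope="session")
def fig8_fronts(fig1_front):
    """Converged fronts for the four 1D-stable gap presets."""
    fronts = {"fig8_row3": fig1_front}  # row 3 repeats the fig1 parameters
    for name in ("fig8_row1", "fig8_row2", "fig8_row4"):
        fronts[name] = solve_front(load_preset(name).params, tol=1e-8)
    return fronts


@pytest.fixture(scope="session")
def benign_front():
    """A transversally stable benign front (weak acid toxicity)."""
    p = ModelParams(a=0.1, kappa=0.1, delta1=0.6, delta2=0.1, delta3=70.0,
                    rho=1.0, eps=0.0063)
    return solve_front(p, tol=1e-8)


@pytest.fixture(scope="session")
def row4_front(fig8_fronts):
    return fig8_fronts["fig8_row4"]


def shooting_layer_speed(w, branch, params) -> float:
    """Independent oracle: heteroclinic speed of the planar layer ODE by
    shooting from the unstable manifold of (v, q) = (0, 0) and bisecting on
    overshoot/undershoot of the target rest state v+(w)."""
    from scipy.integrate import solve_ivp
    from scipy.optimize import brentq

    from acidfront.singular_limit import layer_front

    lf = layer_front(w, branch, params)
    vp, D = lf.v_plus_at_w, lf.diffusion
    rho, d2, a = params.rho, params.delta2, params.a

    def rhs(t, y, c):
        v, q = y
        return [(q + c * v) / D, -rho * v * (1 - v) * (v - a) + d2 * v * w]

    def overshoot(t, y, c):
        return y[0] - vp * 1.0001

    def undershoot(t, y, c):
        return y[0] + 1e-7

    overshoot.terminal = True
    undershoot.terminal = True

    def miss(c):
        g0 = rho * a + d2 * w
        lam = (c / D + np.sqrt((c / D) ** 2 + 4 * g0 / D)) / 2
        d = np.array([1.0, D * lam - c])
        d /= np.linalg.norm(d)
        sol = solve_ivp(rhs, (0, 5000), 1e-8 * d, args=(c,),
                        events=(overshoot, undershoot),
                        rtol=1e-11, atol=1e-14, max_step=20.0)
        if sol.t_events[0].size:
            return 1.0
        if sol.t_events[1].size:
            return -1.0
        return sol.y[0][-1] - vp

    return brentq(miss, -2.5, 2.5, xtol=1e-12)


def random_params(rng, delta3=1.0, eps=0.01) -> ModelParams:
    """Random parameter draw with existing V± (used by sweep tests)."""
    while True:
        a = rng.uniform(0.05, 0.45)
        rho = rng.uniform(0.5, 5.0)
        kappa = rng.uniform(0.05, 0.5)
        d2 = rng.uniform(0.0, 0.3)
        d1 = rng.uniform(0.5, 10.0)
        p = ModelParams(a=a, kappa=kappa, delta1=d1, delta2=d2,
                        delta3=delta3, rho=rho, eps=eps)
        disc = (rho * (1 + a) - d2) ** 2 - 4 * rho * rho * a
        if disc > 1e-4:
            return p
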