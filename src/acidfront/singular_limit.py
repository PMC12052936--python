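"""Singular (eps -> 0) construction of the bistable invasion front.

At eps = 0 the traveling-wave ODE splits into a fast *layer problem* for the
tumor density v near the interface (with acid w frozen) and a slow *reduced
problem* for (w, p = w') on the critical manifolds, which is Hamiltonian.
The front is a concatenation of slow orbit segments and a single fast tanh
jump at the acid level w* fixed by energy matching.  Three concatenations
exist -- benign, malignant no-gap, malignant gap -- distinguished by the
malignancy index delta1*V+ and by whether w* exceeds the transcritical level
1/delta1; in the gap case the slow passage on the tumor-free, normal-cell-free
branch produces an acellular gap of slow width ln(delta1*w*)/sqrt(delta3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .model_core import (
    ModelParams,
    Regime,
    RegimeKind,
    classify_regime,
    equilibrium_V,
)

__all__ = [
    "FoldError",
    "LayerFront",
    "SlowOrbit",
    "SingularFront",
    "fold_bound",
    "v_branch",
    "layer_speed",
    "layer_front",
    "hamiltonian",
    "solve_w_star",
    "slow_orbit",
    "slow_p_plus",
    "singular_front",
    "gap_boundary_delta1",
]


class FoldError(ValueError):
    """Acid level beyond the fold where v+(w) and v-(w) collide."""


def fold_bound(params: ModelParams) -> float:
    """Largest acid level at which the fast branches v±(w) are real.

    Equals rho*(1-a)^2/(4*delta2); infinite when delta2 = 0.
    """
    if params.delta2 == 0.0:
        return np.inf
    return params.rho * (1.0 - params.a) ** 2 / (4.0 * params.delta2)


def v_branch(w: float, params: ModelParams) -> Tuple[float, float]:
    """Tumor rest states v±(w) of the layer problem at frozen acid level w.

    v± = (1 + a ± sqrt((1-a)^2 - 4*delta2*w/rho)) / 2.
    """
    wf = fold_bound(params)
    if w < 0.0 or w > wf:
        raise FoldError(
            f"acid level w={w} outside [0, {wf}] where the fast branches are real"
        )
    disc = (1.0 - params.a) ** 2 - 4.0 * params.delta2 * w / params.rho
    sq = np.sqrt(max(disc, 0.0))
    return (1.0 + params.a + sq) / 2.0, (1.0 + params.a - sq) / 2.0


def _diffusion(branch: int, w: float, params: ModelParams) -> float:
    """Effective v-diffusion in the layer: 1+kappa-u* on the given branch."""
    if branch == 1:
        return params.kappa + params.delta1 * w
    return 1.0 + params.kappa


def layer_speed(w: float, branch: int, params: ModelParams) -> float:
    """Speed of the fast heteroclinic at frozen acid level w.

    c = sqrt(2*rho*D) * (v+(w)/2 - v-(w)) with D the effective diffusion
    (kappa + delta1*w on the invaded branch u = 1-delta1*w, 1+kappa on
    u = 0).  Positive speed means the tumor invades.
    """
    vp, vm = v_branch(w, params)
    D = _diffusion(branch, w, params)
    return np.sqrt(2.0 * params.rho * D) * (vp / 2.0 - vm)


@dataclass(frozen=True)
class LayerFront:
    """Closed-form fast interface at frozen acid level w.

    The profile is v(xi) = (v+/2)(1 + tanh(beta*xi)) with
    beta = (v+/2)*sqrt(rho/(2D)), centered so v(0) = v+/2, together with the
    companion variable q = D*v' - c*v.
    """

    w: float
    branch: int  # 1: u = 1 - delta1*w ; 0: u = 0
    u_star: float
    speed: float
    diffusion: float
    beta: float
    v_plus_at_w: float
    v_minus_at_w: float

    def v(self, xi):
        return 0.5 * self.v_plus_at_w * (1.0 + np.tanh(self.beta * np.asarray(xi)))

    def v_xi(self, xi):
        t = np.cosh(self.beta * np.asarray(xi))
        return 0.5 * self.v_plus_at_w * self.beta / t**2

    def q(self, xi):
        return self.diffusion * self.v_xi(xi) - self.speed * self.v(xi)

    def q_xi(self, xi):
        xi = np.asarray(xi)
        v = self.v(xi)
        # D v'' = (2 beta / v+) (v+ - 2 v) * D v'
        return (2.0 * self.beta / self.v_plus_at_w) * (
            self.v_plus_at_w - 2.0 * v
        ) * self.diffusion * self.v_xi(xi) - self.speed * self.v_xi(xi)


def layer_front(w: float, branch: int, params: ModelParams) -> LayerFront:
    """Construct the fast tanh front on the given branch at acid level w."""
    if branch not in (0, 1):
        raise ValueError("branch must be 0 or 1")
    if branch == 1 and w > 1.0 / params.delta1:
        raise ValueError(
            f"branch 1 requires w <= 1/delta1 = {1.0 / params.delta1:g} "
            f"(u* = 1 - delta1*w must be nonnegative), got w = {w}"
        )
    vp, vm = v_branch(w, params)
    D = _diffusion(branch, w, params)
    u_star = 1.0 - params.delta1 * w if branch == 1 else 0.0
    beta = 0.5 * vp * np.sqrt(params.rho / (2.0 * D))
    return LayerFront(
        w=w, branch=branch, u_star=u_star,
        speed=layer_speed(w, branch, params), diffusion=D, beta=beta,
        v_plus_at_w=vp, v_minus_at_w=vm,
    )


def _int_v_plus(params: ModelParams, w_lo: float, w_hi: float) -> float:
    """Integral of v+(s) ds from w_lo to w_hi by adaptive quadrature."""
    val, _ = quad(
        lambda s: v_branch(s, params)[0], w_lo, w_hi,
        epsabs=1e-12, epsrel=1e-12, limit=200,
    )
    return val


def hamiltonian(w: float, p: float, branch: str, params: ModelParams) -> float:
    """Conserved energy of the reduced slow flow on a critical manifold.

    E_0 = p^2/2 - delta3*w^2/2 on the tumor-free branches (v = 0);
    E_+ = E_0 + delta3*(V+)^2/2 + int_{V+}^{w} delta3*v+(s) ds on the invaded
    branches (v = v+(w)).  Both vanish on the relevant saddle connections.
    """
    d3 = params.delta3
    E0 = 0.5 * p * p - 0.5 * d3 * w * w
    if branch == "M0":
        return E0
    if branch != "Mplus":
        raise ValueError("branch must be 'M0' or 'Mplus'")
    Vpm = equilibrium_V(params)
    if Vpm is None:
        raise ValueError("V+ does not exist for these parameters")
    Vp = Vpm[0]
    if w > fold_bound(params):
        raise FoldError(f"w={w} beyond the fold bound {fold_bound(params)}")
    return E0 + 0.5 * d3 * Vp * Vp + d3 * _int_v_plus(params, Vp, w)


def _matching_function(w: float, params: ModelParams, Vp: float) -> float:
    """(V+)^2 + int_{V+}^{w} (1 + a + sqrt((1-a)^2 - 4*delta2*z/rho)) dz.

    Proportional to E_+(w, sqrt(delta3)*w); its root in (0, V+) is the
    matching acid level w*.
    """
    return Vp * Vp + 2.0 * _int_v_plus(params, Vp, w)


def solve_w_star(params: ModelParams) -> Tuple[float, float]:
    """Acid level w* at which the fast jump occurs, and p* = sqrt(delta3)*w*.

    w* is the unique root in (0, V+) of the energy-matching condition
    E_+(w*, sqrt(delta3)*w*) = 0, i.e. where the unstable manifold of the
    tumor-free saddle meets the stable manifold of the invaded saddle.
    """
    Vpm = equilibrium_V(params)
    if Vpm is None or Vpm[0] <= 0.0:
        raise ValueError("V+ does not exist; no front to match")
    Vp = Vpm[0]
    g = lambda w: _matching_function(w, params, Vp)
    lo, hi = 0.0, Vp
    if g(lo) >= 0.0:
        raise ValueError(
            "no intersection: matching function has no sign change in (0, V+)"
        )
    w_star = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return w_star, np.sqrt(params.delta3) * w_star


def slow_p_plus(w, params: ModelParams):
    """p = w_zeta > 0 along the invaded-branch stable manifold (E_+ = 0).

    p(w) = sqrt(delta3 * (w^2 - (V+)^2 - 2*int_{V+}^{w} v+(s) ds)) for
    w in [w*, V+].
    """
    Vp = equilibrium_V(params)[0]
    w = np.atleast_1d(np.asarray(w, dtype=float))
    out = np.empty_like(w)
    for i, wi in enumerate(w):
        val = wi * wi - Vp * Vp - 2.0 * _int_v_plus(params, Vp, wi)
        out[i] = np.sqrt(params.delta3 * max(val, 0.0))
    return out if out.size > 1 else float(out[0])


@dataclass(frozen=True)
class SlowOrbit:
    """Sampled orbit of the reduced slow flow on a critical manifold branch."""

    branch: str  # "M0" | "Mplus"
    zeta: np.ndarray
    w: np.ndarray
    p: np.ndarray
    energy: float  # conserved Hamiltonian value (0 on the front orbits)

    def v(self, params: ModelParams):
        if self.branch == "M0":
            return np.zeros_like(self.w)
        return np.array([v_branch(wi, params)[0] for wi in self.w])


def slow_orbit(
    branch: str,
    params: ModelParams,
    w_star: float,
    zeta_max: float = None,
    n: int = 400,
    endpoint_tol: float = 1e-6,
) -> SlowOrbit:
    """Sample the slow front segment through (w*, sqrt(delta3)*w*).

    "M0": the unstable manifold of (0,0), w(zeta) = w* exp(sqrt(delta3) zeta)
    for zeta <= 0 (closed form).  "Mplus": the stable-manifold orbit into
    (V+, 0), integrated from (w*, p*) for zeta >= 0 until within
    ``endpoint_tol`` of the equilibrium.  The zeta grid is geometric near 0.
    """
    d3 = params.delta3
    sq = np.sqrt(d3)
    p_star = sq * w_star
    if branch == "M0":
        if zeta_max is None:
            zeta_max = -np.log(endpoint_tol / w_star) / sq
        # geometric refinement toward zeta = 0
        zeta = -np.geomspace(1e-4 * zeta_max, zeta_max, n)[::-1]
        zeta = np.append(zeta, 0.0)
        w = w_star * np.exp(sq * zeta)
        return SlowOrbit("M0", zeta, w, sq * w, 0.0)
    if branch != "Mplus":
        raise ValueError("branch must be 'M0' or 'Mplus'")
    Vp = equilibrium_V(params)[0]

    wf = fold_bound(params)

    def rhs(z, y):
        w, p = y
        # clamp trial evaluations of the integrator into the valid w range
        vp = v_branch(min(max(w, 0.0), wf), params)[0]
        return [p, d3 * (w - vp)]

    def close(z, y):
        return (Vp - y[0]) - endpoint_tol

    close.terminal = True
    # slowest contraction rate at the saddle sets the horizon
    rate = sq * np.sqrt(max(1e-12, 1.0 - _dv_plus(Vp, params)))
    if zeta_max is None:
        zeta_max = -np.log(endpoint_tol / max(Vp - w_star, endpoint_tol)) / rate * 2.0
    sol = solve_ivp(
        rhs, (0.0, zeta_max), [w_star, p_star], events=close,
        rtol=1e-11, atol=1e-13, dense_output=True, max_step=zeta_max / 50,
    )
    if not sol.success:
        raise RuntimeError(
            f"slow-orbit integration failed at zeta={sol.t[-1]:g}: {sol.message}"
        )
    z_end = sol.t_events[0][0] if sol.t_events[0].size else sol.t[-1]
    zeta = np.concatenate([[0.0], np.geomspace(1e-4 * z_end, z_end, n)])
    wz, pz = sol.sol(zeta)
    return SlowOrbit("Mplus", zeta, wz, pz, 0.0)


def _dv_plus(w: float, params: ModelParams) -> float:
    """d v+/dw, used for the saddle contraction rate at (V+, 0)."""
    disc = (1.0 - params.a) ** 2 - 4.0 * params.delta2 * w / params.rho
    if disc <= 0.0:
        return 0.0
    return -params.delta2 / (params.rho * np.sqrt(disc))


@dataclass(frozen=True)
class SingularFront:
    """The eps -> 0 concatenated heteroclinic front."""

    regime: Regime
    w_star: float
    p_star: float
    c_star: float
    jump_branch: int
    segments: List[Tuple[str, Tuple[float, float]]]
    gap_width_zeta: float
    degenerate: bool = False

    @property
    def layer(self) -> "LayerFront":
        raise AttributeError("use singular_front(...).make_layer(params)")

    def make_layer(self, params: ModelParams) -> LayerFront:
        return layer_front(self.w_star, self.jump_branch, params)


def singular_front(params: ModelParams) -> SingularFront:
    """Assemble the singular heteroclinic orbit for the given parameters.

    Segment sequences (in increasing zeta):
      benign:            slow_M0_1 | jump(branch 1) | slow_Mplus_1
      malignant no-gap:  slow_M0_1 | jump(branch 1) | slow_Mplus_1 | slow_Mplus_0
      malignant gap:     slow_M0_1 | slow_M0_0 | jump(branch 0) | slow_Mplus_0
    The singular speed is the layer speed at w*; in the gap case the passage
    on slow_M0_0 (only acid present) has slow width ln(delta1*w*)/sqrt(delta3).
    """
    regime = classify_regime(params)
    if regime.kind is RegimeKind.NO_FRONT:
        raise ValueError("no front: the invaded equilibrium V+ does not exist")
    w_star, p_star = solve_w_star(params)
    Vp = equilibrium_V(params)[0]
    inv_d1 = 1.0 / params.delta1
    degenerate = regime.kind is RegimeKind.DEGENERATE_CROSSOVER

    if regime.kind is RegimeKind.BENIGN:
        segs = [
            ("slow_M0_1", (0.0, w_star)),
            ("jump", (w_star, w_star)),
            ("slow_Mplus_1", (w_star, Vp)),
        ]
        branch, gap = 1, 0.0
    elif regime.kind is RegimeKind.MALIGNANT_NO_GAP or (
        degenerate and w_star <= inv_d1
    ):
        segs = [
            ("slow_M0_1", (0.0, w_star)),
            ("jump", (w_star, w_star)),
            ("slow_Mplus_1", (w_star, inv_d1)),
            ("slow_Mplus_0", (inv_d1, Vp)),
        ]
        branch, gap = 1, 0.0
    else:  # malignant gap
        segs = [
            ("slow_M0_1", (0.0, inv_d1)),
            ("slow_M0_0", (inv_d1, w_star)),
            ("jump", (w_star, w_star)),
            ("slow_Mplus_0", (w_star, Vp)),
        ]
        branch = 0
        gap = np.log(params.delta1 * w_star) / np.sqrt(params.delta3)
    c_star = layer_speed(w_star, branch, params)
    return SingularFront(
        regime=regime, w_star=w_star, p_star=p_star, c_star=c_star,
        jump_branch=branch, segments=segs, gap_width_zeta=gap,
        degenerate=degenerate,
    )


def gap_boundary_delta1(params: ModelParams) -> float:
    """delta1 at the gap onset: the fast jump sits exactly on w = 1/delta1.

    Since the matching level w* does not depend on delta1, the boundary is
    simply delta1 = 1/w*.
    """
    w_star, _ = solve_w_star(params)
    return 1.0 / w_star
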