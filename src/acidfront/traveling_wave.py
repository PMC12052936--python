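"""Fully resolved traveling fronts at finite eps: BVP with unknown speed.

The nu = 0 traveling-wave system is the five-component first-order ODE

    u' = u(1 - u - d1 w)/c,
    v' = (q + c v)/(1 + kappa - u),      q = (1+kappa-u) v' - c v,
    q' = -rho v(1-v)(v-a) + d2 v w,
    w' = eps p,                          p = w'/eps,
    p' = eps (c eps p - d3 (v - w)),

with the wave speed c unknown.  It is solved as a two-point boundary-value
problem on a truncated domain [-L-, L+] split at the interface: both halves
are mapped onto t in [0, 1] and stacked into a ten-component system so that
the phase condition v(0) = v+(w*)/2 (which pins the translation gauge and
pairs with the unknown c) becomes a boundary condition of the stacked
problem.  The far-field ends are closed by projecting the deviation from the
end equilibria onto their stable/unstable eigenspaces, which avoids the
O(exp(-rate L)) speed bias of hard Dirichlet conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp
from scipy.interpolate import interp1d
import scipy.linalg

from .model_core import ModelParams, RegimeKind, equilibrium_V
from .singular_limit import (
    SingularFront,
    singular_front,
    slow_orbit,
    slow_p_plus,
    v_branch,
)

__all__ = [
    "TravelingWave",
    "FrontSolveError",
    "ContinuationBranch",
    "rhs",
    "rhs_jacobian",
    "end_equilibria",
    "initial_guess",
    "solve_front",
    "continue_parameter",
    "measure_gap_width",
]


class FrontSolveError(RuntimeError):
    pass


def rhs(y: np.ndarray, c: float, params: ModelParams) -> np.ndarray:
    """Right-hand side of the five-component traveling-wave ODE.

    ``y`` has shape (5, ...) ordered (u, v, q, w, p).
    """
    u, v, q, w, p = y
    a, k = params.a, params.kappa
    d1, d2, d3, eps = params.delta1, params.delta2, params.delta3, params.eps
    return np.stack(
        [
            u * (1.0 - u - d1 * w) / c,
            (q + c * v) / (1.0 + k - u),
            -params.rho * v * (1.0 - v) * (v - a) + d2 * v * w,
            eps * p,
            eps * (c * eps * p - d3 * (v - w)),
        ]
    )


def rhs_jacobian(y: np.ndarray, c: float, params: ModelParams):
    """(d rhs/d y, d rhs/d c); y shape (5, m) -> jacobians (5, 5, m), (5, m)."""
    u, v, q, w, p = y
    a, k = params.a, params.kappa
    d1, d2, d3, eps, rho = params.delta1, params.delta2, params.delta3, params.eps, params.rho
    m = np.shape(u)
    J = np.zeros((5, 5) + m)
    D = 1.0 + k - u
    J[0, 0] = (1.0 - 2.0 * u - d1 * w) / c
    J[0, 3] = -d1 * u / c
    J[1, 0] = (q + c * v) / D**2
    J[1, 1] = c / D
    J[1, 2] = 1.0 / D
    J[2, 1] = -rho * (-3.0 * v * v + 2.0 * (1.0 + a) * v - a) + d2 * w
    J[2, 3] = d2 * v
    J[3, 4] = eps + np.zeros(m)
    J[4, 1] = -eps * d3 + np.zeros(m)
    J[4, 3] = eps * d3 + np.zeros(m)
    J[4, 4] = c * eps * eps + np.zeros(m)
    dc = np.zeros((5,) + m)
    dc[0] = -u * (1.0 - u - d1 * w) / c**2
    dc[1] = v / D
    dc[4] = eps * eps * p
    return J, dc


def end_equilibria(params: ModelParams, c: float, regime_kind: RegimeKind):
    """Left/right rest states (p2 and p3+ or p4+) in (u, v, q, w, p) space."""
    Vp = equilibrium_V(params)[0]
    left = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    if regime_kind is RegimeKind.BENIGN:
        right = np.array([1.0 - params.delta1 * Vp, Vp, -c * Vp, Vp, 0.0])
        label = "p3+"
    else:
        right = np.array([0.0, Vp, -c * Vp, Vp, 0.0])
        label = "p4+"
    return left, right, label


def _real_invariant_rows(A: np.ndarray, stable: bool) -> np.ndarray:
    """Rows of inv(V) spanning the (un)stable left-invariant subspace of A.

    Complex-conjugate eigenvalue pairs contribute their real and imaginary
    parts, so the returned matrix is real.
    """
    lam, V = scipy.linalg.eig(A)
    B = scipy.linalg.inv(V)  # rows are left eigenvectors
    sel = lam.real < 0.0 if stable else lam.real > 0.0
    rows: List[np.ndarray] = []
    done = np.zeros(len(lam), dtype=bool)
    for i in np.nonzero(sel)[0]:
        if done[i]:
            continue
        if abs(lam[i].imag) > 1e-12:
            rows.append(B[i].real)
            rows.append(B[i].imag)
            # mark the conjugate partner
            j = np.argmin(np.abs(lam - lam[i].conjugate()))
            done[j] = True
        else:
            rows.append(B[i].real)
        done[i] = True
    M = np.array(rows)
    # normalize rows for a well-scaled BC residual
    return M / np.linalg.norm(M, axis=1, keepdims=True)


@dataclass
class TravelingWave:
    """A converged 1D front profile with its wave speed."""

    xi: np.ndarray
    u: np.ndarray
    v: np.ndarray
    q: np.ndarray
    w: np.ndarray
    p: np.ndarray
    c: float
    params: ModelParams
    residual_norm: float
    endpoint_states: Tuple[str, str]
    singular: SingularFront
    L_left: float
    L_right: float
    converged: bool = True

    def profiles(self):
        return np.vstack([self.u, self.v, self.w])

    def interpolant(self, kind: str = "cubic"):
        Y = np.vstack([self.u, self.v, self.q, self.w, self.p])
        return interp1d(
            self.xi, Y, kind=kind, bounds_error=False,
            fill_value=(Y[:, 0], Y[:, -1]),
        )


def _default_lengths(params: ModelParams) -> Tuple[float, float]:
    # slow decay rate in xi is eps*sqrt(delta3); 16 e-foldings keeps the
    # end-state mismatch (dominated by p = sqrt(delta3) w on the slow tail)
    # below 1e-6
    L = 16.0 / (params.eps * np.sqrt(params.delta3))
    return L, L


def _mesh_half(L: float, cluster: Sequence[float], n_coarse: int, n_fine: int) -> np.ndarray:
    """Graded mesh on [0, L]: coarse uniform plus geometric refinement near
    each point of ``cluster`` (given as distances from 0)."""
    pts = [np.linspace(0.0, L, n_coarse)]
    pts.append(np.geomspace(1e-3, min(L, 60.0), n_fine))
    for x0 in cluster:
        if 0.0 < x0 < L:
            local = x0 + np.concatenate(
                [-np.geomspace(0.005, 15.0, n_fine // 2)[::-1],
                 np.geomspace(0.005, 15.0, n_fine // 2)]
            )
            pts.append(local[(local > 0) & (local < L)])
    mesh = np.unique(np.concatenate(pts))
    return mesh[(mesh >= 0.0) & (mesh <= L)]


def initial_guess(
    params: ModelParams,
    L_left: float = None,
    L_right: float = None,
    n_coarse: int = 500,
    n_fine: int = 220,
):
    """Assemble the singular concatenation on a graded xi grid as BVP guess.

    Returns ``(xi_left, Y_left, xi_right, Y_right, c0, sf)`` where the slow
    segments are mapped by zeta = eps*xi, the fast tanh layer is centered at
    xi = 0 and the normal-cell profile is obtained by integrating its
    (stiff, scalar) ODE along the guessed acid profile.
    """
    sf = singular_front(params)
    eps, d1, d3 = params.eps, params.delta1, params.delta3
    Vp = equilibrium_V(params)[0]
    if L_left is None or L_right is None:
        Ld, Rd = _default_lengths(params)
        L_left = L_left or Ld
        L_right = L_right or Rd
    c0 = sf.c_star
    if c0 <= 0.0:
        raise FrontSolveError(
            f"singular speed c* = {c0:g} <= 0: retreating fronts (tumor "
            "regression) are outside the scope of this solver"
        )
    layer = sf.make_layer(params)

    # clusters: the u-transition sits where w crosses 1/delta1
    clusters_left, clusters_right = [], []
    if sf.regime.kind is RegimeKind.MALIGNANT_GAP:
        clusters_left.append(sf.gap_width_zeta / eps)
    elif sf.regime.kind is not RegimeKind.BENIGN:
        # no-gap malignant: crossing on the right slow field
        zc = _zeta_of_w_plus(params, sf.w_star, 1.0 / d1, Vp)
        clusters_right.append(zc / eps)
    xi_l = -_mesh_half(L_left, clusters_left, n_coarse, n_fine)[::-1]
    xi_r = _mesh_half(L_right, clusters_right, n_coarse, n_fine)

    # slow acid profile: exponential on the left, Mplus orbit on the right
    w_l = sf.w_star * np.exp(np.sqrt(d3) * eps * xi_l)
    p_l = np.sqrt(d3) * w_l
    orb = slow_orbit("Mplus", params, sf.w_star, endpoint_tol=1e-9)
    wz = interp1d(orb.zeta, orb.w, kind="cubic", bounds_error=False, fill_value=orb.w[-1])
    pz = interp1d(orb.zeta, orb.p, kind="cubic", bounds_error=False, fill_value=0.0)
    w_r = np.minimum(wz(eps * xi_r), Vp)
    p_r = np.maximum(pz(eps * xi_r), 0.0)

    # tumor profile: tanh layer, modulated toward v+(w) on the right
    v_l = layer.v(xi_l)
    ramp = np.array([v_branch(wi, params)[0] for wi in w_r]) / layer.v_plus_at_w
    v_r = layer.v(xi_r) * ramp

    # normal cells: integrate the stiff scalar ODE along the acid guess
    xi_all = np.concatenate([xi_l, xi_r[1:]])
    w_all = np.concatenate([w_l, w_r[1:]])
    w_of = interp1d(xi_all, w_all, kind="linear", bounds_error=False,
                    fill_value=(w_all[0], w_all[-1]))

    def du(xi, u):
        return u * (1.0 - u - d1 * w_of(xi)) / c0

    u0 = 1.0 - d1 * w_all[0]
    usol = solve_ivp(du, (xi_all[0], xi_all[-1]), [u0], t_eval=xi_all,
                     method="LSODA", rtol=1e-8, atol=1e-10)
    u_all = np.clip(usol.y[0], 0.0, 1.0)
    u_l, u_r = u_all[: len(xi_l)], u_all[len(xi_l) - 1:]

    v_all = np.concatenate([v_l, v_r[1:]])
    dv = np.gradient(v_all, xi_all)
    q_all = (1.0 + params.kappa - u_all) * dv - c0 * v_all
    q_l, q_r = q_all[: len(xi_l)], q_all[len(xi_l) - 1:]

    Y_l = np.vstack([u_l, v_l, q_l, w_l, p_l])
    Y_r = np.vstack([u_r, v_r, q_r, w_r, p_r])
    return xi_l, Y_l, xi_r, Y_r, c0, sf


def _zeta_of_w_plus(params, w_from, w_to, Vp) -> float:
    """Slow time of flight along the Mplus stable-manifold orbit."""
    from scipy.integrate import quad

    val, _ = quad(lambda w: 1.0 / max(slow_p_plus(w, params), 1e-12),
                  w_from, w_to, limit=200)
    return val


def solve_front(
    params: ModelParams,
    guess=None,
    L_left: float = None,
    L_right: float = None,
    tol: float = 1e-8,
    max_nodes: int = 120_000,
    phase_fraction: float = 0.5,
    verbose: int = 0,
) -> TravelingWave:
    """Solve the traveling-wave BVP for the front profile and its speed.

    ``guess`` may be a previously converged :class:`TravelingWave` (used for
    parameter continuation) or ``None`` to start from the singular limit.
    """
    if guess is None:
        xi_l, Y_l, xi_r, Y_r, c0, sf = initial_guess(params, L_left, L_right)
    else:
        sf = singular_front(params)
        c0 = guess.c
        L_l = L_left or guess.L_left
        L_r = L_right or guess.L_right
        f = guess.interpolant()
        # rebuild a fresh graded mesh rather than inheriting the refined
        # one: the collocation solver only ever adds nodes, so reusing the
        # previous mesh makes continuation grow without bound
        clusters_left = []
        if sf.regime.kind is RegimeKind.MALIGNANT_GAP:
            clusters_left.append(sf.gap_width_zeta / params.eps)
        xi_l = -_mesh_half(L_l, clusters_left, 500, 220)[::-1]
        xi_r = _mesh_half(L_r, [], 500, 220)
        Y_l, Y_r = f(xi_l), f(xi_r)
    L_l, L_r = -xi_l[0], xi_r[-1]
    regime_kind = sf.regime.kind
    vp_star = v_branch(sf.w_star, params)[0]
    # phase condition v(0) = phase_fraction * v+(w*); 1/2 centers the tanh
    # layer at xi = 0, other fractions translate the same front
    v_target = phase_fraction * vp_star

    # common collocation grid in t for both halves
    t_l = 1.0 + xi_l / L_l   # left half: xi = -L_l (1 - t)
    t_r = xi_r / L_r         # right half: xi = L_r t
    t = np.unique(np.concatenate([t_l, t_r]))
    t[0], t[-1] = 0.0, 1.0
    # drop near-duplicates from the union of the two half-grids
    keep = np.concatenate([[True], np.diff(t) > 1e-7])
    keep[-1] = True
    t = t[keep]
    if t[-2] >= 1.0 - 1e-7:
        t = np.delete(t, -2)
    fl = interp1d(t_l, Y_l, kind="linear", bounds_error=False,
                  fill_value=(Y_l[:, 0], Y_l[:, -1]))
    fr = interp1d(t_r, Y_r, kind="linear", bounds_error=False,
                  fill_value=(Y_r[:, 0], Y_r[:, -1]))
    Y0 = np.vstack([fl(t), fr(t)])

    def fun(x, Y, pp):
        c = pp[0]
        return np.vstack([L_l * rhs(Y[:5], c, params), L_r * rhs(Y[5:], c, params)])

    def fun_jac(x, Y, pp):
        c = pp[0]
        m = Y.shape[1]
        Jl, dcl = rhs_jacobian(Y[:5], c, params)
        Jr, dcr = rhs_jacobian(Y[5:], c, params)
        J = np.zeros((10, 10, m))
        J[:5, :5] = L_l * Jl
        J[5:, 5:] = L_r * Jr
        dc = np.concatenate([L_l * dcl, L_r * dcr]).reshape(10, 1, m)
        return J, dc

    if c0 <= 0.0:
        raise FrontSolveError(
            f"singular speed c* = {c0:g} <= 0: retreating fronts (tumor "
            "regression) are outside the scope of this solver"
        )

    def bc(ya, yb, pp):
        c = pp[0]
        left_eq, right_eq, _ = end_equilibria(params, c, regime_kind)
        A_l = rhs_jacobian(left_eq, c, params)[0].reshape(5, 5)
        A_r = rhs_jacobian(right_eq, c, params)[0].reshape(5, 5)
        Bs = _real_invariant_rows(A_l, stable=True)     # kill stable part at -L
        Bu = _real_invariant_rows(A_r, stable=False)    # kill unstable part at +L
        if Bs.shape[0] + Bu.shape[0] != 5:
            # dimension counts assume an invading front (c > 0) between
            # saddle end states; a sign change of c during iteration breaks them
            raise FrontSolveError(
                f"end-state eigenvalue counts changed at c={c:g}; "
                "no invading bistable front in this configuration"
            )
        res = np.concatenate([
            Bs @ (ya[:5] - left_eq),
            Bu @ (yb[5:] - right_eq),
            yb[:5] - ya[5:],                 # continuity at xi = 0
            [ya[6] - v_target],              # phase: v(0) = v+(w*)/2
        ])
        return res

    sol = solve_bvp(fun, bc, t, Y0, p=[c0], fun_jac=fun_jac, tol=tol,
                    max_nodes=max_nodes, verbose=verbose)
    if sol.status != 0:
        raise FrontSolveError(
            f"traveling-wave BVP did not converge: {sol.message} "
            f"(max residual {np.max(sol.rms_residuals):.2e}, "
            f"{sol.x.size} nodes)"
        )
    c_h = float(sol.p[0])

    # assemble the profile on the ascending xi grid
    tt = sol.x
    xi = np.concatenate([-L_l * (1.0 - tt), L_r * tt[1:]])
    Y = np.hstack([sol.y[:5], sol.y[5:, 1:]])
    left_eq, right_eq, rlabel = end_equilibria(params, c_h, regime_kind)
    mism = max(np.max(np.abs(Y[:, 0] - left_eq)), np.max(np.abs(Y[:, -1] - right_eq)))
    if mism > 1e-4:
        raise FrontSolveError(
            f"front endpoints off the expected equilibria by {mism:.2e}; "
            "regime mismatch or truncation too short"
        )
    tw = TravelingWave(
        xi=xi, u=Y[0], v=Y[1], q=Y[2], w=Y[3], p=Y[4], c=c_h, params=params,
        residual_norm=float(np.max(sol.rms_residuals)),
        endpoint_states=("p2", rlabel), singular=sf, L_left=L_l, L_right=L_r,
    )
    return tw


@dataclass
class ContinuationBranch:
    """Natural-parameter continuation record along one model parameter."""

    parameter: str
    values: List[float]
    speeds: List[float]
    gap_widths_zeta: List[float]
    regimes: List[str]
    fronts: List[TravelingWave]
    truncated_reason: Optional[str] = None


def continue_parameter(
    front: TravelingWave,
    name: str,
    stop: float,
    max_step: float,
    tol: float = 1e-8,
    keep_fronts: bool = True,
    min_step: float = 1e-4,
) -> ContinuationBranch:
    """Continue a converged front in one parameter up to ``stop``.

    Natural-parameter continuation with adaptive step halving on failure;
    each converged solution seeds the next solve.
    """
    br = ContinuationBranch(name, [], [], [], [], [])

    def record(tw):
        br.values.append(getattr(tw.params, name))
        br.speeds.append(tw.c)
        br.gap_widths_zeta.append(measure_gap_width(tw)[1])
        br.regimes.append(tw.singular.regime.kind.value)
        if keep_fronts:
            br.fronts.append(tw)

    record(front)
    current = front
    val = getattr(front.params, name)
    direction = np.sign(stop - val)
    if direction == 0:
        return br
    step = max_step
    while direction * (stop - val) > 1e-12:
        nxt = val + direction * min(step, abs(stop - val))
        try:
            tw = solve_front(current.params.with_(**{name: nxt}),
                             guess=current, tol=tol)
        except (FrontSolveError, ValueError) as exc:
            step /= 2.0
            if step < min_step:
                br.truncated_reason = f"step underflow at {name}={nxt:g}: {exc}"
                break
            continue
        record(tw)
        current, val = tw, nxt
        step = min(step * 1.5, max_step)
    return br


def measure_gap_width(front: TravelingWave, threshold_multiplier: float = 10.0):
    """Width of the acellular gap: the maximal xi-interval with both
    u < mult*eps and v < mult*eps.  Returns (width_xi, width_zeta)."""
    thr = threshold_multiplier * front.params.eps
    mask = (front.u < thr) & (front.v < thr)
    if not np.any(mask):
        return 0.0, 0.0
    # maximal contiguous run, measured with linear interpolation at the edges
    idx = np.nonzero(mask)[0]
    runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
    best = max(runs, key=lambda r: front.xi[r[-1]] - front.xi[r[0]])
    width = float(front.xi[best[-1]] - front.xi[best[0]])
    return width, width * front.params.eps
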