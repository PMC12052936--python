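"""Transverse (long-wavelength) stability of planar invasion fronts.

Linearizing the comoving 2D model about a 1D front (u_h, v_h, w_h) with
transverse Fourier mode exp(i l y) gives the eigenvalue problem

    L phi = lambda phi + l^2 diag(0, 1+kappa-u_h, 1/eps^2) phi,

where L is the 1D linearization.  Translation invariance puts an eigenvalue
at 0 for l = 0; expanding the critical branch lambda_c(l) = lambda_c2 l^2 +
O(l^4) and eliminating the corrector by Fredholm solvability against the
bounded adjoint null solution yields the curvature coefficient

    lambda_c2 = - int[(1+k-u_h) v_h' vA + (1/eps^2) w_h' wA]
                / int[u_h' uA + v_h' vA + w_h' wA].

A positive lambda_c2 means the planar interface is unstable to long
transverse wavelengths.  The module also evaluates the singular-limit
(eps -> 0) closed-form approximation of lambda_c2 and its sign criterion,
which shows in particular that fronts with an acellular gap are always
transversally unstable when delta2 > 0.

Discretization: second-order finite differences on the (nonuniform) front
grid, node-interleaved for narrow bandwidth; the adjoint is the transpose
of the discrete operator (discrete left null vector = quadrature weights
times the continuous adjoint), so the discrete solvability identity holds
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import quad

from .model_core import ModelParams, RegimeKind
from .singular_limit import (
    layer_front,
    singular_front,
    slow_p_plus,
    solve_w_star,
    v_branch,
)
from .traveling_wave import TravelingWave

__all__ = [
    "LinearizedOperator",
    "AdjointSolution",
    "TransverseReport",
    "assemble_linearization",
    "spectrum",
    "adjoint_null",
    "lambda_c2",
    "lambda_c2_asymptotic",
    "lambda_curve",
    "default_ell_max",
    "stability_boundary",
]


def _fd_weights(x: np.ndarray):
    """Second-order 3-point first/second derivative weights on a nonuniform
    grid; returns (d1m, d1c, d1p, d2m, d2c, d2p) for interior nodes."""
    hm = np.diff(x)[:-1]
    hp = np.diff(x)[1:]
    d1m = -hp / (hm * (hm + hp))
    d1c = (hp - hm) / (hm * hp)
    d1p = hm / (hp * (hm + hp))
    d2m = 2.0 / (hm * (hm + hp))
    d2c = -2.0 / (hm * hp)
    d2p = 2.0 / (hp * (hm + hp))
    return d1m, d1c, d1p, d2m, d2c, d2p


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += 0.5 * dx
    w[1:] += 0.5 * dx
    return w


@dataclass
class LinearizedOperator:
    """Discrete linearization about a front at transverse wavenumber ell.

    ``A`` is the discrete L minus ell^2 * M on interior nodes (Dirichlet at
    the truncated ends), node-interleaved (u_i, v_i, w_i).  ``M`` holds the
    transverse-diffusion weights diag(0, 1+kappa-u_h, 1/eps^2).
    """

    front: TravelingWave
    ell: float
    xi: np.ndarray            # full grid including boundary nodes
    A: sp.csr_matrix
    M: np.ndarray             # (3, n_int) transverse weights on interior nodes
    deriv: np.ndarray         # (3, n_int) analytic front derivative (u', v', w')
    quad_w: np.ndarray        # trapezoid weights on interior nodes
    coeffs: dict = field(default_factory=dict)

    @property
    def n_interior(self) -> int:
        return self.xi.size - 2

    def pack(self, fields3: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(fields3.T).ravel()

    def unpack(self, vec: np.ndarray) -> np.ndarray:
        return vec.reshape(-1, 3).T


def front_derivatives(front: TravelingWave, Y=None):
    """Analytic (u', v', w') and auxiliary (v'', u') along the front, from
    the traveling-wave ODE rather than numerical differentiation.

    ``Y`` optionally supplies (u, v, q, w, p) arrays on another grid (e.g.
    a refined one); defaults to the front's own profile.
    """
    p = front.params
    if Y is None:
        u, v, q, w, pp = front.u, front.v, front.q, front.w, front.p
    else:
        u, v, q, w, pp = Y
    c = front.c
    D = 1.0 + p.kappa - u
    du = u * (1.0 - u - p.delta1 * w) / c
    dv = (q + c * v) / D
    dq = -p.rho * v * (1.0 - v) * (v - p.a) + p.delta2 * v * w
    dw = p.eps * pp
    d2v = (dq + c * dv) / D + (q + c * v) * du / D**2
    return du, dv, dw, d2v


def assemble_linearization(front: TravelingWave, ell: float = 0.0,
                           refine: int = 0) -> LinearizedOperator:
    """Build the sparse discrete operator L - ell^2 M on the front grid.

    ``refine`` bisects every grid interval that many times (profiles are
    re-evaluated from the front interpolant, derivatives analytically);
    useful to push the O(h^2) eigenvalue discretization error down.
    """
    ell = abs(float(ell))
    p = front.params
    xi = front.xi
    if refine > 0:
        for _ in range(refine):
            xi = np.sort(np.concatenate([xi, 0.5 * (xi[1:] + xi[:-1])]))
        Y = front.interpolant()(xi)
        u, v, w = Y[0], Y[1], Y[3]
        du, dv, dw, d2v = front_derivatives(front, Y)
    else:
        u, v, w = front.u, front.v, front.w
        du, dv, dw, d2v = front_derivatives(front)
    n = xi.size
    ni = n - 2
    c = front.c

    a, k = p.a, p.kappa
    d1, d2_, d3, eps, rho = p.delta1, p.delta2, p.delta3, p.eps, p.rho
    Fu = 1.0 - 2.0 * u - d1 * w
    Fw = -d1 * u
    Gv = rho * (-3.0 * v * v + 2.0 * (1.0 + a) * v - a) - d2_ * w
    Gw = -d2_ * v
    Hv = np.full(n, d3)
    Hw = np.full(n, -d3)
    Duu = 1.0 + k - u

    d1m, d1c, d1p, d2m, d2c, d2p = _fd_weights(xi)

    I = np.arange(ni)          # interior node index 0..ni-1 (global node i+1)
    g = lambda arr: arr[1:-1]  # restrict coefficient field to interior

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []

    def add(comp_r, comp_c, diag_vals=None, d1_coef=None, d2_coef=None):
        """Add diag + first/second-derivative stencils from comp_c to comp_r."""
        r = 3 * I + comp_r
        if diag_vals is not None:
            rows.append(r); cols.append(3 * I + comp_c); vals.append(diag_vals)
        for coef, (wm, wc, wp) in (
            ((d1_coef, (d1m, d1c, d1p)),) if d1_coef is not None else ()
        ):
            pass
        if d1_coef is not None:
            _stencil(rows, cols, vals, r, comp_c, d1_coef, d1m, d1c, d1p, I, ni)
        if d2_coef is not None:
            _stencil(rows, cols, vals, r, comp_c, d2_coef, d2m, d2c, d2p, I, ni)

    def _stencil(rows, cols, vals, r, comp_c, coef, wm, wc, wp, I, ni):
        rows.append(r); cols.append(3 * I + comp_c); vals.append(coef * wc)
        m = I > 0
        rows.append(r[m]); cols.append(3 * (I[m] - 1) + comp_c)
        vals.append((coef * wm)[m])
        m = I < ni - 1
        rows.append(r[m]); cols.append(3 * (I[m] + 1) + comp_c)
        vals.append((coef * wp)[m])

    # u-row: -c du/dxi + Fu u + Fw w.  The u equation has no diffusion and
    # Fu vanishes on the transcritical curve, so central differences admit
    # spurious near-null sawtooth modes there (they pollute the adjoint
    # null vector); upwind the advection (c > 0) to damp them.
    r0 = 3 * I + 0
    hm = np.diff(xi)[:-1]
    rows.append(r0); cols.append(3 * I + 0); vals.append(g(Fu) - c / hm)
    m = I > 0
    rows.append(r0[m]); cols.append(3 * (I[m] - 1) + 0)
    vals.append((c / hm)[m])
    add(0, 2, diag_vals=g(Fw))
    # v-row: (-v_h'' - v_h' d/dxi) u + [D d2 - (c + u_h') d1 + Gv - l^2 D] v + Gw w
    add(1, 0, diag_vals=-g(d2v), d1_coef=-g(dv))
    add(1, 1, diag_vals=g(Gv) - ell**2 * g(Duu),
        d1_coef=-(c + g(du)), d2_coef=g(Duu))
    add(1, 2, diag_vals=g(Gw))
    # w-row: Hv v + [(1/eps^2)(d2 - l^2) - c d1 + Hw] w
    add(2, 1, diag_vals=g(Hv))
    add(2, 2, diag_vals=g(Hw) - ell**2 / eps**2, d1_coef=np.full(ni, -c),
        d2_coef=np.full(ni, 1.0 / eps**2))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * ni, 3 * ni),
    )
    M = np.vstack([np.zeros(ni), g(Duu), np.full(ni, 1.0 / eps**2)])
    deriv = np.vstack([g(du), g(dv), g(dw)])
    return LinearizedOperator(
        front=front, ell=ell, xi=xi, A=A, M=M, deriv=deriv,
        quad_w=_trapezoid_weights(xi)[1:-1],
        coeffs=dict(Fu=Fu, Fw=Fw, Gv=Gv, Gw=Gw, Duu=Duu, du=du, dv=dv,
                    dw=dw, d2v=d2v),
    )


@dataclass
class SpectralPoint:
    eigenvalue: complex
    is_translational: bool


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.abs(np.vdot(a, b)) / (na * nb))


def spectrum(
    front: TravelingWave,
    ell: float = 0.0,
    count: int = 40,
    shift: complex = 0.0,
    op: Optional[LinearizedOperator] = None,
):
    """Point eigenvalues of the linearization near ``shift`` (shift-invert).

    Returns (eigenvalues sorted by descending real part, eigenvectors,
    translational flags, operator).  The translational mode is identified by
    eigenvector correlation > 0.99 with the front derivative.
    """
    if op is None or op.ell != abs(ell):
        op = assemble_linearization(front, ell)
    k = min(count, op.A.shape[0] - 2)
    try:
        lam, vecs = spla.eigs(op.A.tocsc(), k=k, sigma=shift, which="LM",
                              maxiter=2000)
    except spla.ArpackNoConvergence:
        # retry with a slightly perturbed shift (shift may coincide with an
        # eigenvalue, which degrades the shift-invert solves)
        lam, vecs = spla.eigs(op.A.tocsc(), k=k, sigma=shift + 1e-4 + 1e-6j,
                              maxiter=5000)
    order = np.argsort(-lam.real)
    lam, vecs = lam[order], vecs[:, order]
    dvec = op.pack(op.deriv)
    flags = np.array([_correlation(vecs[:, i], dvec) > 0.99 for i in range(len(lam))])
    return lam, vecs, flags, op


@dataclass
class AdjointSolution:
    """Bounded null solution of the adjoint linearization at ell = 0.

    ``u_A, v_A, w_A`` approximate the continuous adjoint (the discrete left
    null vector divided by the trapezoid quadrature weights), normalized so
    that the denominator of the solvability quotient equals one.
    """

    xi: np.ndarray
    u_A: np.ndarray
    v_A: np.ndarray
    w_A: np.ndarray
    y: np.ndarray              # raw discrete left null vector (interleaved)
    normalization: float
    op: LinearizedOperator


def adjoint_null(front: TravelingWave, op: Optional[LinearizedOperator] = None) -> AdjointSolution:
    """Left null vector of the discrete linearization (transpose method)."""
    if op is None:
        op = assemble_linearization(front, 0.0)
    AT = op.A.T.tocsc()
    # inverse iteration about 0: the translational eigenvalue of the adjoint
    # is orders of magnitude closer to 0 than the rest of the spectrum, so a
    # handful of LU solves isolates the null vector
    lu = spla.splu(AT - 1e-10 * sp.identity(AT.shape[0], format="csc"))
    rng = np.random.default_rng(7)
    y = rng.standard_normal(AT.shape[0])
    y /= np.linalg.norm(y)
    mu = np.inf
    for _ in range(8):
        y = lu.solve(y)
        y /= np.linalg.norm(y)
        mu_new = float(y @ (AT @ y))
        if abs(mu_new - mu) < 1e-14:
            break
        mu = mu_new
    resid = np.linalg.norm(AT @ y - mu * y)
    scale = spla.norm(op.A, np.inf)
    if resid > 1e-6 * scale:
        raise RuntimeError(
            f"adjoint null vector did not converge (residual {resid:.2e}, "
            f"Rayleigh quotient {mu:.2e}); null space may be degenerate"
        )
    # normalize: denominator of the solvability quotient = 1
    den = float(y @ op.pack(op.deriv))
    y = y / den
    psi = op.unpack(y) / op.quad_w
    return AdjointSolution(
        xi=op.xi[1:-1], u_A=psi[0], v_A=psi[1], w_A=psi[2], y=y,
        normalization=den, op=op,
    )


def lambda_c2(front: TravelingWave, adjoint: Optional[AdjointSolution] = None) -> float:
    """Transverse curvature coefficient by the solvability quotient.

    lambda_c2 = -<M phi', psi> / <phi', psi> with phi' the front derivative,
    psi the adjoint null solution and M = diag(0, 1+kappa-u_h, 1/eps^2).
    """
    if adjoint is None:
        adjoint = adjoint_null(front)
    op = adjoint.op
    num = float(adjoint.y @ op.pack(op.M * op.deriv))
    den = float(adjoint.y @ op.pack(op.deriv))
    if abs(den) < 1e-12:
        raise RuntimeError("solvability denominator vanishes; quotient ill-posed")
    return -num / den


# ---------------------------------------------------------------------------
# singular-limit asymptotics


def _layer_quadratures(params: ModelParams, w_star: float, branch: int):
    """Fast-field integrals of the adjoint asymptotics on the closed-form
    layer: returns (I_vv, I_sign, v_plus_at_wstar)."""
    lf = layer_front(w_star, branch, params)
    c, D, beta, vp = lf.speed, lf.diffusion, lf.beta, lf.v_plus_at_w
    u_star = lf.u_star
    Fu = 1.0 - 2.0 * u_star - params.delta1 * w_star  # < 0 in all regimes
    r = -Fu / c  # decay rate of the u-corrector kernel, > 0 for c > 0

    # grid wide enough for the sech^2 tails yet safe from exp overflow
    X = min(60.0 / beta, 600.0 * D / abs(c)) if c != 0 else 60.0 / beta
    xi = np.linspace(-X, X, 6001)
    vv = lf.v(xi)
    dv = lf.v_xi(xi)
    ekern = np.exp(-c * xi / D)
    vbar = dv * ekern
    d2v = (2.0 * beta / vp) * (vp - 2.0 * vv) * dv
    dvbar = (d2v - (c / D) * dv) * ekern

    I_vv = np.trapezoid(dv * vbar, xi)

    gshape = dv * dvbar  # g = v*' * vbar*'
    # ubar(xi) = (1/c) int_xi^inf exp(-r (s - xi)) g(s) ds, backward recursion
    ubar = np.zeros_like(xi)
    h = np.diff(xi)
    for i in range(len(xi) - 2, -1, -1):
        hi = h[i]
        e = np.exp(-r * hi)
        g0, g1 = gshape[i], gshape[i + 1]
        seg = g0 * (1.0 - e) / r + (g1 - g0) / hi * (1.0 - (1.0 + r * hi) * e) / r**2
        ubar[i] = e * ubar[i + 1] + seg / c
    I_sign = np.trapezoid(
        params.delta1 * u_star * ubar + params.delta2 * vv * vbar, xi
    )
    return I_vv, I_sign, vp


def _slow_integrals(params: ModelParams, w_star: float) -> float:
    """int_{-inf}^0 (w_zeta^-)^2 dzeta + int_0^inf (w_zeta^+)^2 dzeta.

    Ahead of the front the slow orbit is the exponential w* exp(sqrt(d3) z)
    on the acid-only branches (same reduced equation on both), giving
    sqrt(d3) w*^2 / 2; behind, the integral follows the invaded-branch
    stable manifold: int (w_zeta^+)^2 dzeta = int_{w*}^{V+} p(w) dw.
    """
    from .model_core import equilibrium_V

    d3 = params.delta3
    left = np.sqrt(d3) * w_star**2 / 2.0
    Vp = equilibrium_V(params)[0]
    right, _ = quad(lambda w: slow_p_plus(w, params), w_star, Vp, limit=200)
    return left + right


def lambda_c2_asymptotic(params: ModelParams) -> Tuple[float, float]:
    """Leading-order eps -> 0 value and sign of lambda_c2.

    lambda_c2 ~ (1/(eps d3 v*+)) * I_slow / I_vv * I_sign with the fast
    quadratures on the closed-form tanh layer and the slow integrals along
    the reduced orbits; sign(lambda_c2) = sign(I_sign).  In the gap case
    u* = 0, so I_sign = d2 * int v* vbar* > 0 whenever d2 > 0.
    """
    sf = singular_front(params)
    if sf.degenerate:
        raise ValueError(
            "fast jump sits on the transcritical curve; the leading-order "
            "asymptotics do not apply at the degenerate crossover"
        )
    I_vv, I_sign, vp = _layer_quadratures(params, sf.w_star, sf.jump_branch)
    I_slow = _slow_integrals(params, sf.w_star)
    val = I_slow / I_vv * I_sign / (params.eps * params.delta3 * vp)
    return float(val), float(np.sign(I_sign))


@dataclass
class TransverseReport:
    lambda_c2_numeric: float
    lambda_c2_asymptotic: Optional[float]
    asymptotic_sign: Optional[float]
    lambda_curve: Optional[np.ndarray]  # columns (ell, lambda)
    verdict: str


def lambda_curve(
    front: TravelingWave,
    ell_max: float,
    n_points: int = 9,
    count: int = 8,
) -> np.ndarray:
    """Track the critical eigenvalue branch from the translation mode at
    ell = 0; returns an (n, 2) array of (ell, lambda_c)."""
    ells = np.linspace(0.0, ell_max, n_points)
    lam0, vecs, flags, op = spectrum(front, 0.0, count=count, shift=1e-8)
    if not np.any(flags):
        raise RuntimeError("translational eigenvalue not found at ell = 0")
    i0 = int(np.argmax(flags))
    prev_vec = vecs[:, i0]
    # the numerically computed translational eigenvalue sits at O(h^2)
    # instead of exactly 0; subtracting it from the whole branch removes
    # the common discretization bias and enforces the datum lambda_c(0) = 0
    bias = float(lam0[i0].real)
    prev_lam = bias
    out = [(0.0, 0.0)]
    for ell in ells[1:]:
        lam, vecs, flags, _ = spectrum(front, ell, count=count,
                                       shift=prev_lam + 1e-8)
        corr = [_correlation(vecs[:, i], prev_vec) for i in range(len(lam))]
        i = int(np.argmax(corr))
        if corr[i] < 0.9:
            import warnings

            warnings.warn(
                f"eigenvector correlation dropped to {corr[i]:.2f} at ell={ell:g}; "
                "possible branch crossing", stacklevel=2,
            )
        prev_lam, prev_vec = lam[i].real, vecs[:, i]
        out.append((ell, prev_lam - bias))
    return np.array(out)


def fit_lambda_c2(curve: np.ndarray) -> float:
    """Curvature coefficient from a sampled lambda_c(l) branch.

    Least-squares fit of lambda = a*l^2 + b*l^4 (the curve is even in l);
    returns a.  Sampling should stay well inside the long-wavelength regime,
    e.g. l <= default_ell_max(front)/4.
    """
    ell, lam = curve[:, 0], curve[:, 1]
    X = np.vstack([ell**2, ell**4]).T
    coef, *_ = np.linalg.lstsq(X, lam, rcond=None)
    return float(coef[0])


def default_ell_max(front: TravelingWave) -> float:
    """A wavenumber scale on which the quadratic regime of lambda_c(l) is
    resolved: transverse acid diffusion balances the curvature term when
    l ~ eps sqrt(|lambda_c2|); we sample well inside that."""
    lc2 = None
    try:
        lc2, _ = lambda_c2_asymptotic(front.params)
    except ValueError:
        pass
    if lc2 is None or lc2 == 0.0:
        return 0.1
    return 0.5 * front.params.eps * np.sqrt(abs(lc2) * front.params.delta3)


def stability_boundary(
    delta1_values: np.ndarray,
    delta2_bracket: Tuple[float, float],
    base_params: ModelParams,
    n_scan: int = 5,
    tol_delta2: float = 2e-2,
    solve_kwargs: Optional[dict] = None,
):
    """Zero contour of lambda_c2 in the (delta1, delta2) plane.

    For each delta1 the sign of the numeric lambda_c2 is scanned along
    delta2 (warm-starting the front solves) and the contour located by
    bisection.  Returns a list of dicts with the scan and the boundary;
    points where the front solve fails are marked and excluded.
    """
    from .traveling_wave import FrontSolveError, solve_front

    solve_kwargs = solve_kwargs or {}
    results = []
    for d1 in delta1_values:
        lo, hi = delta2_bracket
        scan_d2 = np.linspace(lo, hi, n_scan)
        signs, values = [], []
        guess = None
        for d2 in scan_d2:
            pars = base_params.with_(delta1=float(d1), delta2=float(d2))
            try:
                tw = solve_front(pars, guess=guess, **solve_kwargs)
                guess = tw
                lc2 = lambda_c2(tw)
            except (FrontSolveError, ValueError, RuntimeError) as exc:
                signs.append(None)
                values.append(None)
                continue
            signs.append(np.sign(lc2))
            values.append(lc2)
        # bisect on the first sign change
        boundary = None
        ok = [(d2, s, v) for d2, s, v in zip(scan_d2, signs, values) if s is not None]
        for (d2a, sa, _), (d2b, sb, _) in zip(ok[:-1], ok[1:]):
            if sa != sb:
                a, b = d2a, d2b
                while b - a > tol_delta2:
                    mid = 0.5 * (a + b)
                    pars = base_params.with_(delta1=float(d1), delta2=float(mid))
                    try:
                        tw = solve_front(pars, guess=guess, **solve_kwargs)
                        sm = np.sign(lambda_c2(tw))
                    except (FrontSolveError, ValueError, RuntimeError):
                        break
                    if sm == sa:
                        a = mid
                    else:
                        b = mid
                boundary = 0.5 * (a + b)
                break
        results.append(dict(delta1=float(d1), scan_delta2=scan_d2,
                            signs=signs, values=values, boundary=boundary))
    return results
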