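"""2D comoving-frame simulation of the invasion model and interface
diagnostics.

The full model is evolved in the frame xi = x + c*tau of a 1D front, so an
unperturbed planar front is stationary and any transverse deformation is
directly visible in the interface position h(y).  The acid diffusion is
O(1/eps^2) stiff and is treated implicitly (FFT in the periodic y direction,
tridiagonal solves in xi); the xi-part of the nonlinear tumor diffusion
div((1+kappa-U) grad V) is implicit with the coefficient lagged one step;
reactions, advection and the y-part of the tumor diffusion are explicit.
The xi boundaries are no-flux with a sponge relaxing the outer 5% of the
domain to the end equilibria.

The quantitative contract of this module is linear-regime validation:
fitted growth rates sigma(l_k) of the transverse Fourier modes of h(y)
should match the spectral curve lambda_c(l_k) of the stability module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_banded

from .model_core import ModelParams
from .singular_limit import v_branch
from .traveling_wave import TravelingWave

__all__ = [
    "Field2D",
    "InterfaceDiagnostics",
    "make_initial_condition",
    "evolve",
    "interface_position",
    "mode_amplitudes",
    "mode_growth",
]


@dataclass
class Field2D:
    """Fields (U, V, W) on the comoving 2D grid; arrays are (Ny, Nx)."""

    xi: np.ndarray
    y: np.ndarray
    U: np.ndarray
    V: np.ndarray
    W: np.ndarray
    tau: float
    c: float
    params: ModelParams
    level: float  # interface level: v+(w*)/2 of the seeding front

    def copy(self) -> "Field2D":
        return Field2D(self.xi, self.y, self.U.copy(), self.V.copy(),
                       self.W.copy(), self.tau, self.c, self.params, self.level)


def make_initial_condition(
    front: TravelingWave,
    Ny: int,
    Ly: float,
    noise_amplitude: float = 1e-3,
    seed: int = 0,
    hx: float = 0.1,
    xi_span: Optional[Tuple[float, float]] = None,
    noise_fields: Sequence[str] = ("V",),
) -> Field2D:
    """Extend a 1D front trivially in y and add small seeded noise.

    Noise is uniform in [-amp, amp], independent per grid point, added to
    the fields named in ``noise_fields`` (default: tumor density only).
    """
    params = front.params
    if xi_span is None:
        xi_span = (float(front.xi[0]), float(front.xi[-1]))
    xi = np.arange(xi_span[0], xi_span[1] + 0.5 * hx, hx)
    y = np.linspace(0.0, Ly, Ny, endpoint=False)
    if Ny < 8:
        raise ValueError("Ny too coarse to represent any transverse mode")
    prof = front.interpolant()(xi)
    U = np.tile(prof[0], (Ny, 1))
    V = np.tile(prof[1], (Ny, 1))
    W = np.tile(prof[3], (Ny, 1))
    rng = np.random.default_rng(seed)
    fields = {"U": U, "V": V, "W": W}
    if noise_amplitude > 0.0:
        for name in noise_fields:
            fields[name] += noise_amplitude * rng.uniform(-1.0, 1.0, fields[name].shape)
    level = 0.5 * v_branch(front.singular.w_star, params)[0]
    return Field2D(xi=xi, y=y, U=U, V=V, W=W, tau=0.0, c=front.c,
                   params=params, level=level)


def _tridiag_factor(sub, diag, sup):
    """Banded representation for scipy.solve_banded."""
    n = diag.size
    ab = np.zeros((3, n))
    ab[0, 1:] = sup[:-1]
    ab[1] = diag
    ab[2, :-1] = sub[1:]
    return ab


def _sponge_profile(xi: np.ndarray, frac: float, rate: float) -> np.ndarray:
    L0, L1 = xi[0], xi[-1]
    width = frac * (L1 - L0)
    mu = np.zeros_like(xi)
    mu += rate * np.clip((xi - (L1 - width)) / width, 0.0, 1.0) ** 2
    mu += rate * np.clip(((L0 + width) - xi) / width, 0.0, 1.0) ** 2
    return mu


def evolve(
    state: Field2D,
    dt: float,
    T: float,
    snapshot_stride: int = 50,
    sponge_frac: float = 0.05,
    sponge_rate: float = 1.0,
    record_fields: bool = False,
):
    """March the comoving model forward and record interface diagnostics.

    Returns ``(state, diagnostics)`` where diagnostics is a list of dicts
    with keys tau, h (interface position per y row) and amplitudes |h_hat_k|.
    If ``record_fields`` is set, full field snapshots are kept as well.
    """
    p = state.params
    c = state.c
    xi, y = state.xi, state.y
    Nx, Ny = xi.size, y.size
    hx = xi[1] - xi[0]
    hy = y[1] - y[0]
    U, V, W = state.U, state.V, state.W

    # stability guards for the explicit pieces
    dt_y = hy * hy / (2.0 * (1.0 + p.kappa))
    dt_adv = hx / max(c, 1e-12)
    if dt > min(dt_y, dt_adv):
        raise ValueError(
            f"dt={dt} violates explicit stability: need dt <= "
            f"min(dt_y={dt_y:.3g}, dt_adv={dt_adv:.3g})"
        )

    # end states for inflow/sponge
    left = np.array([U[0, 0], V[0, 0], W[0, 0]])
    right = np.array([U[0, -1], V[0, -1], W[0, -1]])
    mu = _sponge_profile(xi, sponge_frac, sponge_rate)
    targetU = np.where(xi < 0.5 * (xi[0] + xi[-1]), left[0], right[0])
    targetV = np.where(xi < 0.5 * (xi[0] + xi[-1]), left[1], right[1])
    targetW = np.where(xi < 0.5 * (xi[0] + xi[-1]), left[2], right[2])

    # implicit acid operator per transverse mode: (1 + dt*ky^2/eps^2) I
    #   - (dt/eps^2) D2xi  with Neumann ends
    ky = 2.0 * np.pi * np.fft.rfftfreq(Ny, d=hy)
    r = dt / (p.eps**2 * hx**2)
    acid_bands = []
    for k in ky:
        diag = np.full(Nx, 1.0 + dt * k * k / p.eps**2 + 2.0 * r)
        sub = np.full(Nx, -r)
        sup = np.full(Nx, -r)
        diag[0] -= r   # Neumann
        diag[-1] -= r
        acid_bands.append(_tridiag_factor(sub, diag, sup))

    n_steps = int(round(T / dt))
    diagnostics: List[Dict] = []
    snapshots: List[Field2D] = []

    def d_xi_central(A):
        out = np.empty_like(A)
        out[:, 1:-1] = (A[:, 2:] - A[:, :-2]) / (2.0 * hx)
        out[:, 0] = (A[:, 1] - A[:, 0]) / hx
        out[:, -1] = (A[:, -1] - A[:, -2]) / hx
        return out

    def record(tau):
        h = interface_position_fields(V, xi, state.level)
        amps = mode_amplitudes(h)
        diagnostics.append({"tau": tau, "h": h, "amplitudes": amps})
        if record_fields:
            snap = state.copy()
            snap.U, snap.V, snap.W = U.copy(), V.copy(), W.copy()
            snap.tau = tau
            snapshots.append(snap)

    record(state.tau)
    tau = state.tau
    for step in range(1, n_steps + 1):
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(
                f"non-finite fields at tau={tau:.3f}; aborting (last recorded "
                f"diagnostic at tau={diagnostics[-1]['tau']:.3f})"
            )
        # --- U: explicit reaction + upwind advection (+c toward +xi)
        F = U * (1.0 - U) - p.delta1 * U * W
        dUdx = np.empty_like(U)
        dUdx[:, 1:] = (U[:, 1:] - U[:, :-1]) / hx
        dUdx[:, 0] = 0.0  # inflow: held at the left equilibrium
        U_new = U + dt * (F - c * dUdx) - dt * mu * (U - targetU)
        U_new[:, 0] = left[0]

        # --- V: explicit reaction, advection, y-diffusion; implicit xi-diffusion
        G = p.rho * V * (1.0 - V) * (V - p.a) - p.delta2 * V * W
        Dco = 1.0 + p.kappa - U
        flux_y = 0.5 * (Dco + np.roll(Dco, -1, axis=0)) * (
            np.roll(V, -1, axis=0) - V
        ) / hy
        divy = (flux_y - np.roll(flux_y, 1, axis=0)) / hy
        V_star = V + dt * (G - c * d_xi_central(V) + divy) - dt * mu * (V - targetV)
        # xi-part, coefficient lagged (U_new), one tridiagonal solve per row
        Dhalf = 0.5 * (Dco[:, 1:] + Dco[:, :-1])  # (Ny, Nx-1) at i+1/2
        V_new = np.empty_like(V)
        rr = dt / hx**2
        for j in range(Ny):
            dh = Dhalf[j]
            sub = np.empty(Nx); sup = np.empty(Nx); diag = np.empty(Nx)
            sub[1:] = -rr * dh
            sup[:-1] = -rr * dh
            diag[1:-1] = 1.0 + rr * (dh[:-1] + dh[1:])
            diag[0] = 1.0 + rr * dh[0]
            diag[-1] = 1.0 + rr * dh[-1]
            ab = _tridiag_factor(sub, diag, sup)
            V_new[j] = solve_banded((1, 1), ab, V_star[j])

        # --- W: explicit reaction/advection, implicit Laplacian
        H = p.delta3 * (V - W)
        W_star = W + dt * (H - c * d_xi_central(W)) - dt * mu * (W - targetW)
        What = np.fft.rfft(W_star, axis=0)
        for m in range(len(ky)):
            What[m] = solve_banded((1, 1), acid_bands[m], What[m])
        W_new = np.fft.irfft(What, n=Ny, axis=0)

        U, V, W = U_new, V_new, W_new
        tau = state.tau + step * dt
        if step % snapshot_stride == 0 or step == n_steps:
            record(tau)

    state.U, state.V, state.W, state.tau = U, V, W, tau
    return (state, diagnostics, snapshots) if record_fields else (state, diagnostics)


def interface_position_fields(V: np.ndarray, xi: np.ndarray, level: float) -> np.ndarray:
    """Leftmost upward crossing of V through ``level`` per y row (linear
    interpolation); NaN for rows without a crossing."""
    Ny, Nx = V.shape
    below = V < level
    h = np.full(Ny, np.nan)
    cross = below[:, :-1] & ~below[:, 1:]
    for j in range(Ny):
        idx = np.nonzero(cross[j])[0]
        if idx.size == 0:
            continue
        i = idx[0]
        f = (level - V[j, i]) / (V[j, i + 1] - V[j, i])
        h[j] = xi[i] + f * (xi[i + 1] - xi[i])
    return h


def interface_position(state: Field2D, level: Optional[float] = None) -> np.ndarray:
    """Interface position h(y) of a snapshot (level defaults to v+(w*)/2)."""
    return interface_position_fields(
        state.V, state.xi, state.level if level is None else level
    )


def mode_amplitudes(h: np.ndarray) -> np.ndarray:
    """|h_hat(l_k)| of the interface, normalized so that index 0 is the mean
    position and Parseval's identity holds for the remaining modes."""
    hh = np.fft.rfft(h) / h.size
    amp = np.abs(hh)
    amp[1:] *= 2.0  # fold negative frequencies
    if h.size % 2 == 0:
        amp[-1] /= 2.0
    return amp


def mode_growth(
    diagnostics: List[Dict],
    mode_indices: Sequence[int],
    fit_window: Optional[Tuple[float, float]] = None,
    Ly: Optional[float] = None,
):
    """Least-squares growth rates sigma(l_k) of log|h_hat_k| over time.

    ``fit_window`` restricts the fit to tau in [t0, t1]; a warning is issued
    when fewer than 4 snapshots fall in the window.
    """
    taus = np.array([d["tau"] for d in diagnostics])
    amps = np.array([d["amplitudes"] for d in diagnostics])
    if fit_window is not None:
        m = (taus >= fit_window[0]) & (taus <= fit_window[1])
    else:
        m = np.ones_like(taus, dtype=bool)
    if m.sum() < 4:
        import warnings

        warnings.warn("fewer than 4 snapshots in the fit window", stacklevel=2)
    out = {}
    for k in mode_indices:
        a = amps[m, k]
        good = a > 0
        if good.sum() < 2:
            out[k] = np.nan
            continue
        out[k] = float(np.polyfit(taus[m][good], np.log(a[good]), 1)[0])
    return out
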