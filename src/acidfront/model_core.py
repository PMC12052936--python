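"""Model equations, homogeneous steady states and regime classification.

The model is a regularized Gatenby--Gawlinski acid-mediated invasion system
with an Allee effect in the tumor growth law,

    U_t = U(1-U) - d1*U*W,
    V_t = rho*V(1-V)(V-a) - d2*V*W + div((1+kappa-U) grad V),
    W_t = d3*(V-W) + (1/eps^2) Lap W,

for normal-cell density U, tumor-cell density V and acid concentration W.
All quantities are dimensionless.  The module owns the parameter container,
the kinetic terms, the homogeneous background states with their stability,
and the benign / malignant-(no-)gap regime classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "SteadyState",
    "Regime",
    "RegimeKind",
    "reaction_terms",
    "kinetics_jacobian",
    "equilibrium_V",
    "steady_states",
    "classify_regime",
    "dispersion_matrix",
]


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters of the invasion model.

    Parameters
    ----------
    a : Allee threshold of the tumor growth law, 0 < a < 1.
    kappa : diffusion regularization; tumor cells retain mobility
        ``kappa`` even at full normal-cell density.
    delta1 : acid toxicity to normal cells (> 0).
    delta2 : acid toxicity to tumor cells (>= 0, assumed < delta1).
    delta3 : acid production/decay rate (> 0).
    rho : tumor proliferation rate relative to normal cells (> 0).
    eps : scale separation of acid diffusion, 0 < eps << 1.
    nu : frame exponent of the traveling-wave ansatz; only the slow-front
        case nu = 0 is implemented.
    """

    a: float
    kappa: float
    delta1: float
    delta2: float
    delta3: float
    rho: float
    eps: float = 1e-2
    nu: int = field(default=0)

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"Allee threshold a must lie in (0,1), got {self.a}")
        for name in ("kappa", "delta1", "delta3", "rho", "eps"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delta2 < 0.0:
            raise ValueError("delta2 must be nonnegative")
        if self.nu != 0:
            raise NotImplementedError("only slow fronts (nu = 0) are supported")
        if self.delta2 >= self.delta1:
            warnings.warn(
                "model assumption delta2 < delta1 violated "
                f"(delta2={self.delta2}, delta1={self.delta1}); proceeding anyway",
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {
            "a": self.a, "kappa": self.kappa, "delta1": self.delta1,
            "delta2": self.delta2, "delta3": self.delta3, "rho": self.rho,
            "eps": self.eps,
        }


class RegimeKind(str, Enum):
    BENIGN = "benign"
    MALIGNANT_NO_GAP = "malignant_no_gap"
    MALIGNANT_GAP = "malignant_gap"
    DEGENERATE_CROSSOVER = "degenerate_crossover"
    NO_FRONT = "no_front"


@dataclass(frozen=True)
class SteadyState:
    """A homogeneous background state with its kinetic stability."""

    label: str  # one of P1, P2, P3+, P3-, P4+, P4-
    UVW: tuple
    relevant: bool
    stability: str  # stable | unstable | not_applicable


@dataclass(frozen=True)
class Regime:
    """Front-type classification of a parameter set."""

    kind: RegimeKind
    w_star: Optional[float]
    malignancy_index: Optional[float]  # delta1 * V+


def reaction_terms(u, v, w, params: ModelParams):
    """Kinetic rates (F, G, H) of the three species.

    F = u(1-u) - d1*u*w,  G = rho*v(1-v)(v-a) - d2*v*w,  H = d3*(v-w).
    Accepts scalars or arrays; rejects non-finite input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
        raise ValueError("reaction_terms requires finite (u, v, w)")
    F = u * (1.0 - u) - params.delta1 * u * w
    G = params.rho * v * (1.0 - v) * (v - params.a) - params.delta2 * v * w
    H = params.delta3 * (v - w)
    return F, G, H


def kinetics_jacobian(u, v, w, params: ModelParams) -> np.ndarray:
    """3x3 Jacobian of (F, G, H) with respect to (u, v, w)."""
    a, d1, d2, d3, rho = params.a, params.delta1, params.delta2, params.delta3, params.rho
    Gv = rho * (-3.0 * v * v + 2.0 * (1.0 + a) * v - a) - d2 * w
    return np.array(
        [
            [1.0 - 2.0 * u - d1 * w, 0.0, -d1 * u],
            [0.0, Gv, -d2 * v],
            [0.0, d3, -d3],
        ]
    )


def equilibrium_V(params: ModelParams):
    """Nontrivial tumor equilibria V± of rho*(1-V)(V-a) = d2*V.

    Roots of ``rho V^2 - (rho(1+a) - d2) V + rho a = 0``.  Returns
    ``(V_plus, V_minus)`` or ``None`` when the discriminant is negative.
    """
    rho, a, d2 = params.rho, params.a, params.delta2
    b = rho * (1.0 + a) - d2
    disc = b * b - 4.0 * rho * rho * a
    if disc < 0.0:
        return None
    sq = np.sqrt(disc)
    return (b + sq) / (2.0 * rho), (b - sq) / (2.0 * rho)


_STAB_TOL = 1e-9


def _stability_label(J: np.ndarray) -> str:
    mx = np.max(np.real(np.linalg.eigvals(J)))
    if mx < -_STAB_TOL:
        return "stable"
    if mx > _STAB_TOL:
        return "unstable"
    return "not_applicable"


def steady_states(params: ModelParams):
    """All homogeneous background states with admissibility and stability.

    P1 = (0,0,0) and P2 = (1,0,0) always exist; P3± = (1-d1 V±, V±, V±) and
    P4± = (0, V±, V±) exist when V± are real.  Stability is read off the
    kinetics Jacobian eigenvalues; this reproduces the model facts that P2 is
    stable, P1/P3-/P4- are unstable, P3+ is stable iff d1 V+ < 1 and P4+ is
    stable iff d1 V+ > 1.
    """
    d1 = params.delta1
    out = []

    def add(label, U, V, W, relevant):
        J = kinetics_jacobian(U, V, W, params)
        out.append(SteadyState(label, (U, V, W), relevant, _stability_label(J)))

    add("P1", 0.0, 0.0, 0.0, True)
    add("P2", 1.0, 0.0, 0.0, True)
    Vpm = equilibrium_V(params)
    if Vpm is not None:
        for sign, V in zip(("+", "-"), Vpm):
            add(f"P3{sign}", 1.0 - d1 * V, V, V, V > 0.0 and 1.0 - d1 * V > 0.0)
            add(f"P4{sign}", 0.0, V, V, V > 0.0)
    return out


#: tolerance on |delta1 * w_star - 1| below which the fast jump sits on the
#: transcritical curve and the concatenation is degenerate
CROSSOVER_TOL = 1e-8


def classify_regime(params: ModelParams) -> Regime:
    """Classify the front type for a parameter set.

    benign when d1 V+ < 1 (normal cells survive behind the front);
    malignant otherwise, split into gap / no-gap by whether the matching
    acid level w* exceeds the transcritical level 1/d1.
    """
    # imported here: singular_limit depends on this module
    from .singular_limit import solve_w_star

    Vpm = equilibrium_V(params)
    if Vpm is None or Vpm[0] <= 0.0:
        return Regime(RegimeKind.NO_FRONT, None, None)
    Vp = Vpm[0]
    idx = params.delta1 * Vp
    w_star, _ = solve_w_star(params)
    if idx < 1.0:
        return Regime(RegimeKind.BENIGN, w_star, idx)
    gap_measure = params.delta1 * w_star - 1.0
    if abs(gap_measure) < CROSSOVER_TOL:
        kind = RegimeKind.DEGENERATE_CROSSOVER
    elif gap_measure > 0.0:
        kind = RegimeKind.MALIGNANT_GAP
    else:
        kind = RegimeKind.MALIGNANT_NO_GAP
    return Regime(kind, w_star, idx)


def dispersion_matrix(state_UVW, k, params: ModelParams) -> np.ndarray:
    """Linearization of the full PDE about a homogeneous state at wavenumber k.

    Returns J - k^2 diag(0, 1+kappa-U, 1/eps^2); not used by the front
    machinery but handy for checking essential-spectrum boundaries.
    """
    U, V, W = state_UVW
    J = kinetics_jacobian(U, V, W, params)
    D = np.diag([0.0, 1.0 + params.kappa - U, 1.0 / params.eps**2])
    return J - (k * k) * D
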