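"""Mass-action kinetics of ligand-induced receptor modulation.

One receptor-expressing unit exposed to a local ligand concentration ``L``
(nM) carries four receptor sub-populations (continuous counts):

* ``R``       free surface receptors,
* ``LR_act``  active (signaling) receptor-ligand complexes,
* ``LR_des``  desensitized surface complexes,
* ``R_int``   internalized receptors awaiting re-expression.

The scheme is the standard homologous-desensitization recycling loop for
G-protein-coupled chemoattractant receptors (measured on human neutrophil
formyl peptide receptors):

.. code-block:: text

    R + L  --k_f·L-->  LR_act  --k_des-->  LR_des  --k_i-->  R_int
      ^     <--k_r--                                           |
      |______________________k_up______________________________|

Ligand dissociation from desensitized surface complexes is taken as
negligible, and the internalized complex / intracellular free receptor are
merged into the single recycling pool ``R_int`` (exactly one transition per
published rate constant).  Total receptor number per unit is conserved:
``R + LR_act + LR_des + R_int = R_u`` at all times.

Internal units: time in seconds, concentrations in nM, receptor amounts as
continuous counts; ``k_f`` is stored in nM^-1 s^-1 (0.084 == 8.4e7 M^-1 s^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .exceptions import DomainError, ParameterError, StepSizeError

__all__ = [
    "KineticParams",
    "ReceptorPoolState",
    "table1_desensitizable",
    "table1_nondesensitizable",
    "KINETIC_PRESETS",
    "initial_state",
    "derivative",
    "rate_matrix",
    "rk4_propagator",
    "integrate",
    "steady_state",
]

#: Relative tolerance below which a negative overshoot is clamped to zero
#: rather than treated as an integration failure.
NEGATIVITY_TOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and receptor endowment for one ligand-receptor pair.

    Parameters
    ----------
    k_f : float
        Ligand-receptor association rate, nM^-1 s^-1.
    k_r : float
        (Low-affinity) ligand-receptor dissociation rate, s^-1.
    k_des : float
        Homologous desensitization rate, s^-1.  0 models a
        nondesensitizable receptor.
    k_i : float
        Internalization rate of desensitized complexes, s^-1.
    k_up : float
        Up-regulation (re-expression) rate of internalized receptors, s^-1.
    R_u : float
        Receptor endowment of one receptor-expressing unit (counts).
    """

    k_f: float = 0.084
    k_r: float = 0.37
    k_des: float = 0.065
    k_i: float = 0.0033
    k_up: float = 0.004
    R_u: float = 12500.0

    def __post_init__(self) -> None:
        for name in ("k_f", "k_r", "k_des", "k_i", "k_up"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.R_u) or self.R_u <= 0:
            raise ParameterError(f"R_u must be finite and > 0, got {self.R_u!r}")
        if self.k_des > 0 and (self.k_i <= 0 or self.k_up <= 0):
            # otherwise the desensitized/internalized pools are absorbing and
            # no steady state with nonzero flux exists
            raise ParameterError(
                "k_des > 0 requires k_i > 0 and k_up > 0 "
                f"(got k_des={self.k_des}, k_i={self.k_i}, k_up={self.k_up})"
            )

    def replace(self, **changes) -> "KineticParams":
        """Return a copy with the given fields overridden."""
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def table1_desensitizable(R_u: float = 12500.0) -> KineticParams:
    """Neutrophil formyl-peptide-receptor rates, desensitizable variant."""
    return KineticParams(k_f=0.084, k_r=0.37, k_des=0.065, k_i=0.0033,
                         k_up=0.004, R_u=R_u)


def table1_nondesensitizable(R_u: float = 12500.0) -> KineticParams:
    """Same rates with k_des = 0 (nondesensitizable receptor mutant)."""
    return KineticParams(k_f=0.084, k_r=0.37, k_des=0.0, k_i=0.0033,
                         k_up=0.004, R_u=R_u)


KINETIC_PRESETS: dict[str, Callable[..., KineticParams]] = {
    "table1_desensitizable": table1_desensitizable,
    "table1_nondesensitizable": table1_nondesensitizable,
}


@dataclass(frozen=True)
class ReceptorPoolState:
    """The four receptor sub-populations of one unit for one ligand."""

    R: float
    LR_act: float
    LR_des: float
    R_int: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.LR_act, self.LR_des, self.R_int], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ReceptorPoolState":
        R, LR_act, LR_des, R_int = (float(x) for x in arr)
        return cls(R, LR_act, LR_des, R_int)

    @property
    def total(self) -> float:
        return self.R + self.LR_act + self.LR_des + self.R_int


def _check_state(state: ReceptorPoolState) -> np.ndarray:
    arr = state.as_array()
    if np.any(arr < 0):
        raise DomainError(f"state components must be >= 0, got {state}")
    return arr


def initial_state(params: KineticParams) -> ReceptorPoolState:
    """All receptors start on the surface in the free state."""
    return ReceptorPoolState(R=params.R_u, LR_act=0.0, LR_des=0.0, R_int=0.0)


def rate_matrix(L: float, params: KineticParams) -> np.ndarray:
    """4x4 matrix M with d(state)/dt = M @ state at ligand concentration L.

    The kinetics are linear in the state for fixed L; every column of M sums
    to zero (conservation of the flow).
    """
    if L < 0 or not math.isfinite(L):
        raise DomainError(f"ligand concentration must be finite and >= 0, got {L!r}")
    kf, kr, kdes, ki, kup = params.k_f, params.k_r, params.k_des, params.k_i, params.k_up
    b = kf * L
    return np.array(
        [
            [-b, kr, 0.0, kup],
            [b, -(kr + kdes), 0.0, 0.0],
            [0.0, kdes, -ki, 0.0],
            [0.0, 0.0, ki, -kup],
        ]
    )


def derivative(state: ReceptorPoolState, L: float, params: KineticParams) -> ReceptorPoolState:
    """Instantaneous rate of change (per second) of the four pools.

    dR/dt      = -k_f L R + k_r LR_act + k_up R_int
    dLR_act/dt =  k_f L R - (k_r + k_des) LR_act
    dLR_des/dt =  k_des LR_act - k_i LR_des
    dR_int/dt  =  k_i LR_des - k_up R_int
    """
    arr = _check_state(state)
    return ReceptorPoolState.from_array(rate_matrix(L, params) @ arr)


def rk4_propagator(M: np.ndarray, dt: float) -> np.ndarray:
    """One-step propagator of classical RK4 applied to x' = M x.

    For a linear constant-coefficient system the RK4 update is exactly the
    degree-4 Taylor polynomial of the matrix exponential:
    ``x(t+dt) = (I + A + A^2/2 + A^3/6 + A^4/24) x(t)`` with ``A = dt*M``.
    Works on stacked matrices (…, 4, 4).
    """
    A = dt * M
    A2 = A @ A
    A3 = A2 @ A
    A4 = A3 @ A
    eye = np.broadcast_to(np.eye(M.shape[-1]), M.shape).copy()
    return eye + A + A2 / 2.0 + A3 / 6.0 + A4 / 24.0


def _clamp_negatives(arr: np.ndarray, R_u, dt: float | None = None) -> np.ndarray:
    """Clamp tiny negative overshoot; raise StepSizeError for large overshoot."""
    low = arr.min()
    if low < 0:
        tol = NEGATIVITY_TOL * np.min(R_u)
        if low < -tol:
            hint = f" (dt={dt})" if dt is not None else ""
            raise StepSizeError(
                f"integration produced component {low:.3g} < -{tol:.3g}; "
                f"reduce the RK4 step size{hint}"
            )
        arr = np.clip(arr, 0.0, None)
    return arr


def integrate(
    state0: ReceptorPoolState,
    ligand_trace: Union[float, Callable[[float], float]],
    params: KineticParams,
    dt: float = 0.1,
    duration: float = 0.0,
) -> ReceptorPoolState:
    """Integrate the kinetics with classical RK4 over ``[0, duration]`` (s).

    ``ligand_trace`` is either a constant concentration (nM) or a callable
    ``t -> L(t)``; it must be non-negative over the whole interval.  The
    final partial step, if any, uses a shortened dt so the integration ends
    exactly at ``duration``.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt!r}")
    if duration < 0:
        raise ParameterError(f"duration must be >= 0, got {duration!r}")
    arr = _check_state(state0)
    if duration == 0:
        return state0

    if not callable(ligand_trace):
        # constant ligand: the RK4 update is the exact polynomial propagator
        # of the linear system, so n steps are one matrix power (identical
        # algebra, see rk4_propagator)
        L_const = float(ligand_trace)
        P = rk4_propagator(rate_matrix(L_const, params), dt)
        n_full, rem = divmod(duration, dt)
        out = np.linalg.matrix_power(P, int(round(n_full))) @ arr
        if rem > 1e-12 * max(duration, dt):
            out = rk4_propagator(rate_matrix(L_const, params), rem) @ out
        if not np.all(np.isfinite(out)):
            raise StepSizeError(
                f"RK4 diverged at dt={dt} (L={L_const} nM); reduce the step size"
            )
        out = _clamp_negatives(out, params.R_u, dt)
        return ReceptorPoolState.from_array(out)

    L_of_t = ligand_trace

    n_full, rem = divmod(duration, dt)
    steps = [dt] * int(round(n_full))
    if rem > 1e-12 * max(duration, dt):
        steps.append(rem)

    t = 0.0
    for h in steps:
        # classical RK4 with the ligand sampled at t, t+h/2, t+h
        L0 = float(L_of_t(t))
        Lm = float(L_of_t(t + 0.5 * h))
        L1 = float(L_of_t(t + h))
        for L in (L0, Lm, L1):
            if L < 0:
                raise DomainError(f"ligand_trace returned {L} < 0 at t~{t}")
        M0 = rate_matrix(L0, params)
        Mm = rate_matrix(Lm, params)
        M1 = rate_matrix(L1, params)
        k1 = M0 @ arr
        k2 = Mm @ (arr + 0.5 * h * k1)
        k3 = Mm @ (arr + 0.5 * h * k2)
        k4 = M1 @ (arr + h * k3)
        arr = arr + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        arr = _clamp_negatives(arr, params.R_u, dt)
        t += h
    return ReceptorPoolState.from_array(arr)


def steady_state(L: float, params: KineticParams) -> ReceptorPoolState:
    """Closed-form steady state of the recycling loop at fixed L (nM).

    Setting the four derivatives to zero under total receptor conservation:

        LR_act = R_u k_f L / [(k_r + k_des) + k_f L (1 + k_des/k_i + k_des/k_up)]
        LR_des = (k_des/k_i)  LR_act
        R_int  = (k_des/k_up) LR_act
        R      = R_u - LR_act - LR_des - R_int

    With k_des = 0 the recycling terms vanish and LR_act reduces exactly to
    the Langmuir isotherm R_u L / (k_r/k_f + L).
    """
    if L < 0 or not math.isfinite(L):
        raise DomainError(f"ligand concentration must be finite and >= 0, got {L!r}")
    kf, kr, kdes, ki, kup, R_u = (
        params.k_f, params.k_r, params.k_des, params.k_i, params.k_up, params.R_u,
    )
    if L == 0 or kf == 0:
        return ReceptorPoolState(R=R_u, LR_act=0.0, LR_des=0.0, R_int=0.0)
    recyc = (kdes / ki + kdes / kup) if kdes > 0 else 0.0
    LR_act = R_u * kf * L / ((kr + kdes) + kf * L * (1.0 + recyc))
    LR_des = (kdes / ki) * LR_act if kdes > 0 else 0.0
    R_int = (kdes / kup) * LR_act if kdes > 0 else 0.0
    R = R_u - LR_act - LR_des - R_int
    return ReceptorPoolState(R=R, LR_act=LR_act, LR_des=LR_des, R_int=R_int)


def steady_state_active(L, params: KineticParams):
    """Vectorized steady-state LR_act for an array of ligand concentrations."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise DomainError("ligand concentrations must be >= 0")
    kf, kr, kdes = params.k_f, params.k_r, params.k_des
    recyc = (kdes / params.k_i + kdes / params.k_up) if kdes > 0 else 0.0
    with np.errstate(invalid="ignore"):
        out = params.R_u * kf * L / ((kr + kdes) + kf * L * (1.0 + recyc))
    return np.where(L == 0, 0.0, out)
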