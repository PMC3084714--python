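"""Stochastic agent-based 2-D cell migration in ligand gradient fields.

Each migration step:

1. the net orientation vector ``v`` is computed from the cell's current
   (dynamically integrated) receptor states;
2. the step (persistence) time is proportional to |v| with an optimal step
   of ``tau_opt`` = 2.5 min:  ``tau = clamp(tau_opt*|v|/v_sat, tau_min,
   tau_opt)``;
3. if |v| >= threshold the cell turns toward ``arg(v)`` through multiple
   sub-steps at an angular speed proportional to |v| (normalized so
   |v| = v_sat completes a pi turn within one optimal step), capped so it
   never overshoots the target; below the threshold the cell re-orients to
   a uniformly random direction and migrates for ``tau_min`` (chemokinesis);
4. during every sub-step the cell advances ``speed * substep_dt`` along its
   current heading while the receptor states of all units are integrated
   (classical RK4, step ``ode_dt``) against the local ligand concentrations
   at the unit positions.

Within one sub-step (0.05 min = 3 s by default; the cell moves 0.5 um) the
ligand concentration at each unit is frozen at its sub-step-start value,
which makes the kinetics linear with constant coefficients; the RK4 update
is then applied as its exact polynomial propagator (see
:func:`chemonav.kinetics.rk4_propagator`) raised to the number of ODE steps
per sub-step — algebraically identical to stepwise RK4, but much cheaper.

Motion never pauses, so every track's path length is exactly
``speed * total_time``.  All randomness comes from one seeded generator per
track; draws occur in a fixed order (one uniform heading at track start,
then one uniform angle per random-mode step), so tracks are bit-for-bit
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ParameterError, StepSizeError
from .fields import LigandEnvironment
from .kinetics import (
    KineticParams,
    NEGATIVITY_TOL,
    rk4_propagator,
    steady_state_active,
)
from .orientation import (
    DIRECTED_THRESHOLD,
    CellGeometry,
    OrientationVector,
    orientation_from_states,
    unit_positions,
)

__all__ = [
    "MigrationConfig",
    "CellState",
    "Track",
    "advance_step",
    "simulate_track",
    "simulate_population",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class MigrationConfig:
    """Migration-model settings (lengths um, times min, rates s^-1)."""

    speed: float = 10.0          # um/min
    threshold: float = DIRECTED_THRESHOLD  # receptor counts
    tau_opt: float = 2.5         # min, optimal (maximal) step time
    tau_min: float = 0.25        # min, shortest step time
    v_sat: float = 100.0         # counts at which the step time saturates
    substep_dt: float = 0.05     # min, turning/advection sub-step
    ode_dt: float = 0.1          # s, RK4 step for the receptor kinetics
    total_time: float = 75.0     # min
    seed: int = 0
    steady_state_sensing: bool = False  # memoryless variant for comparison

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ParameterError(f"speed must be > 0, got {self.speed!r}")
        if not (0 < self.tau_min <= self.tau_opt):
            raise ParameterError(
                f"need 0 < tau_min <= tau_opt, got {self.tau_min}, {self.tau_opt}"
            )
        if not (self.v_sat >= self.threshold > 0):
            raise ParameterError(
                f"need v_sat >= threshold > 0, got v_sat={self.v_sat}, "
                f"threshold={self.threshold}"
            )
        if not (0 < self.substep_dt <= self.tau_min):
            raise ParameterError(
                f"need 0 < substep_dt <= tau_min, got {self.substep_dt}"
            )
        if self.ode_dt <= 0:
            raise ParameterError(f"ode_dt must be > 0, got {self.ode_dt!r}")
        n_ode = round(self.substep_dt * 60.0 / self.ode_dt)
        if n_ode < 1 or abs(n_ode * self.ode_dt - self.substep_dt * 60.0) > 1e-9:
            raise ParameterError(
                "substep_dt (in seconds) must be an integer multiple of ode_dt"
            )

    @property
    def n_ode_per_substep(self) -> int:
        return round(self.substep_dt * 60.0 / self.ode_dt)

    def replace(self, **changes) -> "MigrationConfig":
        return replace(self, **changes)


@dataclass
class CellState:
    """Position, heading and full receptor state of one migrating cell.

    ``receptor_states`` maps ligand_id -> (n_units, 4) array with columns
    (R, LR_act, LR_des, R_int) in unit order.
    """

    position: np.ndarray
    heading: float
    receptor_states: dict[str, np.ndarray]
    geometry: CellGeometry = field(default_factory=CellGeometry)

    def copy(self) -> "CellState":
        return CellState(
            position=self.position.copy(),
            heading=self.heading,
            receptor_states={k: v.copy() for k, v in self.receptor_states.items()},
            geometry=self.geometry,
        )

    def orientation(self) -> OrientationVector:
        return orientation_from_states(self.receptor_states, self.geometry)


@dataclass
class Track:
    """Time-stamped trajectory of one simulated cell.

    mode[i] is the stepping mode ("directed" or "random") of the migration
    step that produced sample i; net_mag[i] is the orientation magnitude
    evaluated at the start of that step.  Sample 0 is the start position.
    """

    t: np.ndarray          # min
    x: np.ndarray          # um
    y: np.ndarray          # um
    heading: np.ndarray    # rad, in [0, 2pi)
    net_mag: np.ndarray    # receptor counts
    mode: np.ndarray       # "directed" | "random"
    track_id: int = 0

    def __len__(self) -> int:
        return self.t.size

    @property
    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def net_displacement(self) -> float:
        return float(math.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    @property
    def final_position(self) -> np.ndarray:
        return np.array([self.x[-1], self.y[-1]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.t,
                "x_um": self.x,
                "y_um": self.y,
                "heading_rad": self.heading,
                "net_mag": self.net_mag,
                "mode": self.mode,
            }
        )


def _rate_matrices(L: np.ndarray, p: KineticParams) -> np.ndarray:
    """(n, 4, 4) kinetic matrices for a vector of ligand concentrations."""
    n = L.shape[0]
    M = np.zeros((n, 4, 4))
    b = p.k_f * L
    M[:, 0, 0] = -b
    M[:, 0, 1] = p.k_r
    M[:, 0, 3] = p.k_up
    M[:, 1, 0] = b
    M[:, 1, 1] = -(p.k_r + p.k_des)
    M[:, 2, 1] = p.k_des
    M[:, 2, 2] = -p.k_i
    M[:, 3, 2] = p.k_i
    M[:, 3, 3] = -p.k_up
    return M


def _integrate_substep(
    states: np.ndarray, L: np.ndarray, p: KineticParams, ode_dt: float, n_ode: int
) -> np.ndarray:
    """Advance (n_units, 4) states by n_ode RK4 steps at frozen per-unit L."""
    P = rk4_propagator(_rate_matrices(L, p), ode_dt)
    Pk = np.linalg.matrix_power(P, n_ode)
    out = np.einsum("nij,nj->ni", Pk, states)
    low = out.min()
    if low < 0:
        if low < -NEGATIVITY_TOL * p.R_u:
            raise StepSizeError(
                f"receptor integration produced {low:.3g} < 0; reduce ode_dt"
            )
        out = np.clip(out, 0.0, None)
    return out


def _steady_orientation(cell: CellState, env, params_by_ligand) -> OrientationVector:
    vx = vy = 0.0
    dirs = cell.geometry.unit_directions
    upos = unit_positions(cell.position, cell.geometry)
    for lig in env.ligand_ids:
        L = env.ligand_concentration_at(lig, upos[:, 0], upos[:, 1])
        lr = steady_state_active(L, params_by_ligand[lig])
        v = (4.0 / cell.geometry.n_units) * (lr[:, None] * dirs).sum(axis=0)
        vx += v[0]
        vy += v[1]
    return OrientationVector(float(vx), float(vy))


def advance_step(
    cell: CellState,
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    config: MigrationConfig,
    rng: np.random.Generator,
    max_time: Optional[float] = None,
) -> tuple[CellState, list[tuple[float, float, float, float, float, str]]]:
    """Advance the cell by one migration step.

    Returns the new cell state and the sub-step samples
    ``(dt_from_step_start_min, x, y, heading, net_mag, mode)``; ``max_time``
    (min) truncates the step so a track ends exactly at its total time.
    """
    cell = cell.copy()
    if config.steady_state_sensing:
        v = _steady_orientation(cell, env, params_by_ligand)
    else:
        v = cell.orientation()
    mag = v.magnitude

    tau = min(max(config.tau_opt * mag / config.v_sat, config.tau_min), config.tau_opt)
    directed = mag >= config.threshold
    if directed:
        target = math.atan2(v.vy, v.vx)
        omega = (math.pi / config.tau_opt) * (mag / config.v_sat)  # rad/min
        mode = "directed"
    else:
        # chemokinesis: instantaneous re-orientation to a uniformly random
        # heading, shortest persistence
        target = rng.uniform(0.0, TWO_PI)
        cell.heading = target
        omega = 0.0
        tau = config.tau_min
        mode = "random"

    n_sub = max(1, round(tau / config.substep_dt))
    if max_time is not None:
        n_sub = min(n_sub, max(1, round(max_time / config.substep_dt)))
    h = config.substep_dt
    n_ode = config.n_ode_per_substep

    samples = []
    x, y = float(cell.position[0]), float(cell.position[1])
    heading = cell.heading
    for i in range(n_sub):
        if omega > 0.0:
            diff = (target - heading + math.pi) % TWO_PI - math.pi
            step = min(omega * h, abs(diff))
            heading = (heading + math.copysign(step, diff)) % TWO_PI
        # freeze the per-unit ligand concentrations at the sub-step start
        upos = unit_positions((x, y), cell.geometry)
        for lig in env.ligand_ids:
            L = env.ligand_concentration_at(lig, upos[:, 0], upos[:, 1])
            cell.receptor_states[lig] = _integrate_substep(
                cell.receptor_states[lig], L, params_by_ligand[lig], config.ode_dt, n_ode
            )
        x += config.speed * h * math.cos(heading)
        y += config.speed * h * math.sin(heading)
        samples.append(((i + 1) * h, x, y, heading, mag, mode))

    cell.position = np.array([x, y])
    cell.heading = heading % TWO_PI
    return cell, samples


def _fresh_states(
    params_by_ligand: Mapping[str, KineticParams],
    env: LigandEnvironment,
    geometry: CellGeometry,
) -> dict[str, np.ndarray]:
    """All receptors initially on the surface in the free state."""
    states = {}
    for lig in env.ligand_ids:
        s = np.zeros((geometry.n_units, 4))
        s[:, 0] = params_by_ligand[lig].R_u
        states[lig] = s
    return states


def simulate_track(
    start,
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    geometry: CellGeometry = CellGeometry(),
    config: MigrationConfig = MigrationConfig(),
    track_id: int = 0,
) -> Track:
    """Simulate one cell for ``config.total_time`` minutes from ``start``."""
    if config.total_time <= 0:
        raise ParameterError(f"total_time must be > 0, got {config.total_time!r}")
    for lig in env.ligand_ids:
        if lig not in params_by_ligand:
            raise ParameterError(f"no kinetic parameters for ligand {lig!r}")
    rng = np.random.default_rng(config.seed)
    start = np.asarray(start, dtype=float)
    cell = CellState(
        position=start.copy(),
        heading=rng.uniform(0.0, TWO_PI),
        receptor_states=_fresh_states(params_by_ligand, env, geometry),
        geometry=geometry,
    )

    ts = [0.0]
    xs = [start[0]]
    ys = [start[1]]
    headings = [cell.heading]
    mags = [0.0]
    modes = ["random"]
    t = 0.0
    eps = 1e-9
    first = True
    while t < config.total_time - eps:
        cell, samples = advance_step(
            cell, env, params_by_ligand, config, rng, max_time=config.total_time - t
        )
        if first:
            # sample 0 carries the mode/magnitude of the first evaluation
            mags[0] = samples[0][4]
            modes[0] = samples[0][5]
            first = False
        for dt_rel, x, y, hd, mag, mode in samples:
            ts.append(t + dt_rel)
            xs.append(x)
            ys.append(y)
            headings.append(hd)
            mags.append(mag)
            modes.append(mode)
        t = ts[-1]

    return Track(
        t=np.asarray(ts),
        x=np.asarray(xs),
        y=np.asarray(ys),
        heading=np.asarray(headings),
        net_mag=np.asarray(mags),
        mode=np.asarray(modes, dtype=object),
        track_id=track_id,
    )


def simulate_population(
    starts,
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    geometry: CellGeometry = CellGeometry(),
    config: MigrationConfig = MigrationConfig(),
    base_seed: Optional[int] = None,
) -> list[Track]:
    """Independent tracks, one per start; track i uses seed base_seed + i."""
    starts = list(starts)
    if not starts:
        raise ParameterError("starts must be non-empty")
    if base_seed is None:
        base_seed = config.seed
    return [
        simulate_track(
            s, env, params_by_ligand, geometry,
            config.replace(seed=base_seed + i), track_id=i,
        )
        for i, s in enumerate(starts)
    ]
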