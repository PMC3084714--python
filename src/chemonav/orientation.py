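"""Cell geometry and orientation vectors (front-back differences in LR*).

The model cell is a ring of ``n_units`` receptor-expressing units at radius
``r`` from the center of mass (default: 4 units on the +/-x and +/-y axes,
r = 5 um for a 10-um-diameter cell).  For each ligand, the orientation
vector is the difference of active receptor-ligand complexes (LR*) across
the cell:

* 4 units:  ``vx = LR*(+x) - LR*(-x)``, ``vy = LR*(+y) - LR*(-y)``;
* N units:  ``v = (4/N) * sum_j LR*_j d_hat_j`` — the continuum
  generalization, normalized so it reduces exactly to the 4-unit
  definition at N = 4.

The net orientation vector in a multi-ligand environment is the sum of the
per-ligand vectors.  A cell is chemotactically *directed* when the net
magnitude |dLR*| reaches the threshold (10 receptor counts by default,
the minimal occupancy difference for sensing a ~1% concentration
difference across the cell length); comparison is inclusive (>= 10 counts
as directed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError
from .fields import LigandEnvironment
from .kinetics import KineticParams, ReceptorPoolState, steady_state_active

__all__ = [
    "CellGeometry",
    "OrientationVector",
    "unit_positions",
    "ligand_orientation_steady",
    "net_orientation_steady",
    "orientation_from_states",
    "orientation_map",
    "sweep_orientation",
    "DIRECTED_THRESHOLD",
]

#: Default threshold magnitude of the orientation vector for chemotactic
#: orientation (receptor counts); |dLR*| >= threshold counts as directed.
DIRECTED_THRESHOLD = 10.0


@dataclass(frozen=True)
class CellGeometry:
    """Ring of receptor-expressing units around the cell center."""

    unit_radius: float = 5.0  # um
    n_units: int = 4

    def __post_init__(self) -> None:
        if self.unit_radius <= 0:
            raise ParameterError(f"unit_radius must be > 0, got {self.unit_radius!r}")
        if self.n_units < 4 or self.n_units % 4 != 0:
            raise ParameterError(
                f"n_units must be a multiple of 4 and >= 4, got {self.n_units!r}"
            )

    @property
    def unit_directions(self) -> np.ndarray:
        """(n_units, 2) unit vectors, evenly spaced, first along +x.

        For the axis-aligned units the tiny floating-point residues of
        cos/sin at multiples of pi/2 are snapped to exact 0/±1.
        """
        ang = 2.0 * np.pi * np.arange(self.n_units) / self.n_units
        d = np.column_stack([np.cos(ang), np.sin(ang)])
        d[np.abs(d) < 1e-12] = 0.0
        d[np.abs(d - 1.0) < 1e-12] = 1.0
        d[np.abs(d + 1.0) < 1e-12] = -1.0
        return d


@dataclass(frozen=True)
class OrientationVector:
    """Front-back LR* difference vector (receptor-count units)."""

    vx: float
    vy: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.vx, self.vy)

    def as_array(self) -> np.ndarray:
        return np.array([self.vx, self.vy], dtype=float)

    def is_directed(self, threshold: float = DIRECTED_THRESHOLD) -> bool:
        return self.magnitude >= threshold


def unit_positions(center, geometry: CellGeometry) -> np.ndarray:
    """(n_units, 2) positions of the receptor-expressing units (um)."""
    c = np.asarray(center, dtype=float)
    return c[None, :] + geometry.unit_radius * geometry.unit_directions


def _combine(lr_per_unit: np.ndarray, geometry: CellGeometry) -> OrientationVector:
    v = (4.0 / geometry.n_units) * (lr_per_unit[:, None] * geometry.unit_directions).sum(axis=0)
    return OrientationVector(float(v[0]), float(v[1]))


def ligand_orientation_steady(
    position,
    env: LigandEnvironment,
    ligand_id: str,
    params: KineticParams,
    geometry: CellGeometry = CellGeometry(),
) -> OrientationVector:
    """Steady-state orientation vector toward one ligand's gradient."""
    pos = unit_positions(position, geometry)
    L = env.ligand_concentration_at(ligand_id, pos[:, 0], pos[:, 1])
    lr = steady_state_active(L, params)
    return _combine(lr, geometry)


def net_orientation_steady(
    position,
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    geometry: CellGeometry = CellGeometry(),
) -> OrientationVector:
    """Sum of the steady-state orientation vectors over all ligands present."""
    vx = vy = 0.0
    for lig in env.ligand_ids:
        if lig not in params_by_ligand:
            raise ConfigurationError(
                f"no kinetic parameters for ligand {lig!r} (have "
                f"{sorted(params_by_ligand)})"
            )
        v = ligand_orientation_steady(position, env, lig, params_by_ligand[lig], geometry)
        vx += v.vx
        vy += v.vy
    return OrientationVector(vx, vy)


def orientation_from_states(
    per_unit_states: Mapping[str, Sequence],
    geometry: CellGeometry = CellGeometry(),
) -> OrientationVector:
    """Orientation vector from dynamically integrated receptor states.

    ``per_unit_states`` maps ligand_id to the per-unit states in unit order:
    either a sequence of :class:`ReceptorPoolState` or an (n_units, 4) array
    with LR* in column 1.
    """
    vx = vy = 0.0
    for lig, states in per_unit_states.items():
        if isinstance(states, np.ndarray):
            if states.shape != (geometry.n_units, 4):
                raise ConfigurationError(
                    f"state array for ligand {lig!r} has shape {states.shape}, "
                    f"expected {(geometry.n_units, 4)}"
                )
            lr = states[:, 1]
        else:
            if len(states) != geometry.n_units:
                raise ConfigurationError(
                    f"{len(states)} states for ligand {lig!r}, expected {geometry.n_units}"
                )
            lr = np.array([s.LR_act for s in states], dtype=float)
        v = _combine(lr, geometry)
        vx += v.vx
        vy += v.vy
    return OrientationVector(vx, vy)


def _net_orientation_grid(
    points: np.ndarray,
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    geometry: CellGeometry,
) -> np.ndarray:
    """Vectorized net steady orientation for (m, 2) points -> (m, 2)."""
    dirs = geometry.unit_directions  # (n, 2)
    upos = points[:, None, :] + geometry.unit_radius * dirs[None, :, :]  # (m, n, 2)
    out = np.zeros((points.shape[0], 2))
    for lig in env.ligand_ids:
        if lig not in params_by_ligand:
            raise ConfigurationError(f"no kinetic parameters for ligand {lig!r}")
        L = env.ligand_concentration_at(lig, upos[..., 0], upos[..., 1])  # (m, n)
        lr = steady_state_active(L, params_by_ligand[lig])
        out += (4.0 / geometry.n_units) * np.einsum("mn,nd->md", lr, dirs)
    return out


def orientation_map(
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    geometry: CellGeometry = CellGeometry(),
    bbox: tuple[float, float, float, float] = (-1000.0, -1000.0, 1000.0, 1000.0),
    step: float = 50.0,
    threshold: float = DIRECTED_THRESHOLD,
) -> pd.DataFrame:
    """Steady-state orientation-vector map on a regular grid.

    Returns columns ``x_um, y_um, vx, vy, directed`` (directed means the net
    magnitude reaches the threshold).
    """
    if step <= 0:
        raise ParameterError(f"step must be > 0, got {step!r}")
    x0, y0, x1, y1 = bbox
    if x1 < x0 or y1 < y0:
        raise ParameterError(f"degenerate bbox {bbox!r}")
    nx = int(math.ceil((x1 - x0) / step)) + 1 if x1 > x0 else 1
    ny = int(math.ceil((y1 - y0) / step)) + 1 if y1 > y0 else 1
    xs = x0 + step * np.arange(nx)
    ys = y0 + step * np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    v = _net_orientation_grid(pts, env, params_by_ligand, geometry)
    mag = np.hypot(v[:, 0], v[:, 1])
    return pd.DataFrame(
        {
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "vx": v[:, 0],
            "vy": v[:, 1],
            "directed": mag >= threshold,
        }
    )


_SWEEPABLE = {"k_des", "k_i", "k_up", "k_des1"}


def sweep_orientation(
    param_name: str,
    values: Sequence[float],
    positions: Sequence,
    env: LigandEnvironment,
    params_by_ligand: Mapping[str, KineticParams],
    geometry: CellGeometry = CellGeometry(),
    axis_target=None,
) -> pd.DataFrame:
    """Signed orientation strength vs a swept receptor-modulation rate.

    ``k_des``, ``k_i``, ``k_up`` override the rate for *every* ligand;
    ``k_des1`` overrides the desensitization rate of the first ligand only
    (the others keep their configured rates).  At each (position, value)
    the net steady orientation vector is projected onto the unit vector
    from the position toward ``axis_target`` (default: the center of the
    environment's first field), so positive values mean orientation toward
    that source.

    Returns columns ``param, value, position_id, x_um, y_um, component``.
    """
    if param_name not in _SWEEPABLE:
        raise ParameterError(
            f"unknown sweep parameter {param_name!r}; choose from {sorted(_SWEEPABLE)}"
        )
    if not env.fields:
        raise ConfigurationError("environment has no fields to sweep against")
    if axis_target is None:
        axis_target = env.fields[0].center
    target = np.asarray(axis_target, dtype=float)
    ligands = env.ligand_ids

    rows = []
    for value in values:
        if value < 0:
            raise ParameterError(f"swept rate must be >= 0, got {value!r}")
        if param_name == "k_des1":
            pbl = dict(params_by_ligand)
            first = ligands[0]
            pbl[first] = params_by_ligand[first].replace(k_des=value)
        else:
            field_name = {"k_des": "k_des", "k_i": "k_i", "k_up": "k_up"}[param_name]
            pbl = {
                lig: p.replace(**{field_name: value}) for lig, p in params_by_ligand.items()
            }
        for pid, pos in enumerate(positions):
            p = np.asarray(pos, dtype=float)
            v = net_orientation_steady(p, env, pbl, geometry)
            axis = target - p
            norm = np.linalg.norm(axis)
            comp = float(v.as_array() @ (axis / norm)) if norm > 0 else 0.0
            rows.append(
                {
                    "param": param_name,
                    "value": float(value),
                    "position_id": pid,
                    "x_um": p[0],
                    "y_um": p[1],
                    "component": comp,
                }
            )
    return pd.DataFrame(rows)
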