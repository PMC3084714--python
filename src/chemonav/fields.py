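"""Fixed nonlinear 2-D ligand concentration fields.

A chemoattractant source is modeled as a radially symmetric bounded power
gradient centered at a point: ``L(rho) = L_0 + (L_max - L_0) (1 - rho/A)^n``
for ``rho <= A`` and exactly ``L_0`` beyond the field radius ``A``.  The
default parameters (L_max 17.6 nM, L_0 0, A 1000 um, n 3) give the fixed
nonlinear profile that approximates point-source diffusion of a ~10 kDa
chemokine.

Multiple sources of the *same* ligand superpose (concentrations add);
distinct ligands coexist without summing and are sensed by distinct
receptor pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = ["PowerGradientField", "LigandEnvironment", "grid_sample"]


@dataclass(frozen=True)
class PowerGradientField:
    """One radially symmetric power-gradient ligand source."""

    ligand_id: str
    center: tuple[float, float] = (0.0, 0.0)
    L_max: float = 17.6   # nM, peak concentration at the center
    L_0: float = 0.0      # nM, basal concentration outside the field
    A: float = 1000.0     # um, field radius
    n: float = 3.0        # power of the gradient profile

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise ParameterError("ligand_id must be a non-empty label")
        if not (self.L_max > self.L_0 >= 0):
            raise ParameterError(
                f"need L_max > L_0 >= 0, got L_max={self.L_max}, L_0={self.L_0}"
            )
        if self.A <= 0 or self.n <= 0:
            raise ParameterError(f"need A > 0 and n > 0, got A={self.A}, n={self.n}")
        if len(self.center) != 2 or not all(math.isfinite(c) for c in self.center):
            raise ParameterError(f"center must be a finite (x, y) point, got {self.center}")

    def concentration(self, point) -> float:
        """Ligand concentration (nM) at a point (um, um) of the plane."""
        px, py = float(point[0]), float(point[1])
        rho = math.hypot(px - self.center[0], py - self.center[1])
        if rho >= self.A:
            return self.L_0
        return self.L_0 + (self.L_max - self.L_0) * (1.0 - rho / self.A) ** self.n

    def concentration_at(self, x, y) -> np.ndarray:
        """Vectorized concentration over arrays of coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x - self.center[0], y - self.center[1])
        inside = rho < self.A
        out = np.full(np.broadcast_shapes(x.shape, y.shape), self.L_0, dtype=float)
        out[inside] = self.L_0 + (self.L_max - self.L_0) * (1.0 - rho[inside] / self.A) ** self.n
        return out


@dataclass(frozen=True)
class LigandEnvironment:
    """A collection of power-gradient sources, possibly of several ligands."""

    fields: tuple[PowerGradientField, ...] = ()

    def __init__(self, fields=()):
        object.__setattr__(self, "fields", tuple(fields))

    @property
    def ligand_ids(self) -> tuple[str, ...]:
        """Distinct ligand labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for f in self.fields:
            seen.setdefault(f.ligand_id, None)
        return tuple(seen)

    def fields_of(self, ligand_id: str) -> tuple[PowerGradientField, ...]:
        return tuple(f for f in self.fields if f.ligand_id == ligand_id)

    def ligand_concentration(self, ligand_id: str, point) -> float:
        """Sum of the concentrations of all sources of one ligand (nM)."""
        return sum(f.concentration(point) for f in self.fields_of(ligand_id))

    def ligand_concentration_at(self, ligand_id: str, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=float)
        for f in self.fields_of(ligand_id):
            out += f.concentration_at(x, y)
        return out


def grid_sample(
    env: LigandEnvironment,
    ligand_id: str,
    bbox: tuple[float, float, float, float],
    step: float,
) -> pd.DataFrame:
    """Sample one ligand's concentration on a regular grid.

    Returns a DataFrame with columns ``x_um, y_um, L_nM``; the grid covers
    ``[x0, x1] x [y0, y1]`` inclusive with the given step (the last row or
    column may extend one step past the bbox edge to include it).
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
    L = env.ligand_concentration_at(ligand_id, X, Y)
    return pd.DataFrame({"x_um": X.ravel(), "y_um": Y.ravel(), "L_nM": L.ravel()})
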