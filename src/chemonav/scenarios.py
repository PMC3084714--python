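"""Named scenario presets, config serialization, CSV I/O, track metrics.

The presets mirror the study's gradient configurations:

* ``single_{2,20,200}nM_{desens,nondesens}`` — one power-gradient source,
  7 cells started on a ring at rho = 900 um, 150 min.
* ``opposing_{desens,nondesens,mixed}`` — two different ligands with
  identical profiles facing each other across the cells (sources on the
  x-axis at +/-700 um), 12 cells along the axis, 75 min.  ``mixed`` =
  nondesensitizable receptor for L1, desensitizable for L2.
* ``angled_{same,diff}_{desens,nondesens}``, ``angled_mixed`` — two sources
  1150 um apart forming a roughly equilateral triangle with the start
  cluster (~900 um from each source), 9 cells, 75 min.  ``same`` = both
  sources emit one ligand (their fields superpose); ``diff`` = two
  distinct ligands.
* ``nav_A..nav_D`` — multi-step navigation toward a distant target L3
  (150 min, 9 cells, desensitizable receptors): A = distant L3 alone
  (outside detection range of the starts), B = L3 plus one nearer source,
  C = L3 plus an angled pair of one identical ligand, D = L3 plus an
  angled pair of two different ligands.
* ``orientmap_single``, ``orientmap_opposing`` — steady-state map
  scenarios (no starts).

Source separations and start coordinates are conventions of this package
(the study prints none); they are config-overridable.  The opposing-preset
separation of 1400 um is deliberate: see docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ParameterError, ScenarioNotFoundError
from .fields import LigandEnvironment, PowerGradientField
from .kinetics import KineticParams, table1_desensitizable, table1_nondesensitizable
from .migration import MigrationConfig, Track
from .orientation import CellGeometry

__all__ = [
    "Scenario",
    "TrackMetrics",
    "build_scenario",
    "list_scenarios",
    "track_metrics",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
    "write_tracks_csv",
    "read_tracks_csv",
]

# ---------------------------------------------------------------------------
# scenario container

@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation setup."""

    name: str
    env: LigandEnvironment
    params_by_ligand: dict[str, KineticParams]
    geometry: CellGeometry = field(default_factory=CellGeometry)
    starts: tuple[tuple[float, float], ...] = ()
    migration: MigrationConfig = field(default_factory=MigrationConfig)

    def __post_init__(self) -> None:
        for lig in self.env.ligand_ids:
            if lig not in self.params_by_ligand:
                raise ConfigurationError(
                    f"scenario {self.name!r}: ligand {lig!r} has no parameter set"
                )

    def source_labels(self) -> dict[str, tuple[float, float]]:
        """Stable labels for the field centers: ligand_id, suffixed .0, .1,…
        when one ligand has several sources."""
        out: dict[str, tuple[float, float]] = {}
        counts: dict[str, int] = {}
        for f in self.env.fields:
            counts[f.ligand_id] = counts.get(f.ligand_id, 0) + 1
        seen: dict[str, int] = {}
        for f in self.env.fields:
            if counts[f.ligand_id] == 1:
                out[f.ligand_id] = f.center
            else:
                j = seen.get(f.ligand_id, 0)
                seen[f.ligand_id] = j + 1
                out[f"{f.ligand_id}.{j}"] = f.center
        return out


# ---------------------------------------------------------------------------
# preset geometry conventions (um); see docs/methods.md for the rationale
# behind the opposing/angled source separations

_ANGLED_HALF_SEP = 575.0
_ANGLED_Y = 575.0 * math.sqrt(3.0)        # 995.93: sources at (+/-575, 995.93)
_OPPOSING_HALF_SEP = 700.0                # sources at (+/-700, 0)
_NAV_L3_CENTER = (0.0, 1340.0)
_NAV_B_L1_CENTER = (0.0, 1100.0)


def _ring_starts(radius: float, n: int) -> tuple[tuple[float, float], ...]:
    ang = 2.0 * np.pi * np.arange(n) / n
    return tuple((radius * math.cos(a), radius * math.sin(a)) for a in ang)


def _cluster_starts() -> tuple[tuple[float, float], ...]:
    """3x3 start cluster on the triangle bisector, inside the detection band."""
    return tuple((x, y) for y in (260.0, 300.0, 340.0) for x in (-40.0, 0.0, 40.0))


def _axis_starts(n: int = 12, half_span: float = 250.0) -> tuple[tuple[float, float], ...]:
    xs = np.linspace(-half_span, half_span, n)
    return tuple((float(x), 0.0) for x in xs)


def _single_field(ligand: str, L_max: float, center=(0.0, 0.0)) -> PowerGradientField:
    return PowerGradientField(ligand_id=ligand, center=center, L_max=L_max)


def _desens() -> KineticParams:
    return table1_desensitizable()


def _nondesens() -> KineticParams:
    return table1_nondesensitizable()


def _make_single(L_max: float, desensitizable: bool, name: str) -> Scenario:
    p = _desens() if desensitizable else _nondesens()
    return Scenario(
        name=name,
        env=LigandEnvironment([_single_field("L", L_max)]),
        params_by_ligand={"L": p},
        starts=_ring_starts(900.0, 7),
        migration=MigrationConfig(total_time=150.0),
    )


def _make_opposing(p1: KineticParams, p2: KineticParams, name: str) -> Scenario:
    env = LigandEnvironment(
        [
            _single_field("L1", 17.6, center=(-_OPPOSING_HALF_SEP, 0.0)),
            _single_field("L2", 17.6, center=(+_OPPOSING_HALF_SEP, 0.0)),
        ]
    )
    return Scenario(
        name=name,
        env=env,
        params_by_ligand={"L1": p1, "L2": p2},
        starts=_axis_starts(),
        migration=MigrationConfig(total_time=75.0),
    )


def _angled_pair(same_ligand: bool) -> list[PowerGradientField]:
    left, right = (-_ANGLED_HALF_SEP, _ANGLED_Y), (_ANGLED_HALF_SEP, _ANGLED_Y)
    if same_ligand:
        return [_single_field("L1", 17.6, left), _single_field("L1", 17.6, right)]
    return [_single_field("L1", 17.6, left), _single_field("L2", 17.6, right)]


def _make_angled(same_ligand: bool, p1: KineticParams,
                 p2: Optional[KineticParams], name: str) -> Scenario:
    env = LigandEnvironment(_angled_pair(same_ligand))
    params = {"L1": p1} if same_ligand else {"L1": p1, "L2": p2}
    return Scenario(
        name=name,
        env=env,
        params_by_ligand=params,
        starts=_cluster_starts(),
        migration=MigrationConfig(total_time=75.0),
    )


def _make_nav(name: str) -> Scenario:
    l3 = _single_field("L3", 17.6, _NAV_L3_CENTER)
    if name == "nav_A":
        fields = [l3]
        params = {"L3": _desens()}
    elif name == "nav_B":
        fields = [_single_field("L1", 17.6, _NAV_B_L1_CENTER), l3]
        params = {"L1": _desens(), "L3": _desens()}
    elif name == "nav_C":
        fields = _angled_pair(same_ligand=True) + [l3]
        params = {"L1": _desens(), "L3": _desens()}
    elif name == "nav_D":
        fields = _angled_pair(same_ligand=False) + [l3]
        params = {"L1": _desens(), "L2": _desens(), "L3": _desens()}
    else:  # pragma: no cover
        raise ScenarioNotFoundError(name)
    return Scenario(
        name=name,
        env=LigandEnvironment(fields),
        params_by_ligand=params,
        starts=_cluster_starts(),
        migration=MigrationConfig(total_time=150.0),
    )


def _make_orientmap(name: str) -> Scenario:
    if name == "orientmap_single":
        env = LigandEnvironment([_single_field("L", 17.6)])
        params = {"L": _desens()}
    else:
        env = LigandEnvironment(
            [
                _single_field("L1", 17.6, center=(-_OPPOSING_HALF_SEP, 0.0)),
                _single_field("L2", 17.6, center=(+_OPPOSING_HALF_SEP, 0.0)),
            ]
        )
        params = {"L1": _desens(), "L2": _desens()}
    return Scenario(name=name, env=env, params_by_ligand=params, starts=())


_PRESETS = {}
for _lmax, _tag in ((2.0, "2nM"), (20.0, "20nM"), (200.0, "200nM")):
    _PRESETS[f"single_{_tag}_desens"] = (
        lambda lm=_lmax, nm=f"single_{_tag}_desens": _make_single(lm, True, nm)
    )
    _PRESETS[f"single_{_tag}_nondesens"] = (
        lambda lm=_lmax, nm=f"single_{_tag}_nondesens": _make_single(lm, False, nm)
    )
_PRESETS.update(
    {
        "opposing_desens": lambda: _make_opposing(_desens(), _desens(), "opposing_desens"),
        "opposing_nondesens": lambda: _make_opposing(
            _nondesens(), _nondesens(), "opposing_nondesens"
        ),
        # mixed: nondesensitizable receptor for L1, desensitizable for L2
        "opposing_mixed": lambda: _make_opposing(_nondesens(), _desens(), "opposing_mixed"),
        "angled_same_desens": lambda: _make_angled(True, _desens(), None, "angled_same_desens"),
        "angled_diff_desens": lambda: _make_angled(
            False, _desens(), _desens(), "angled_diff_desens"
        ),
        "angled_same_nondesens": lambda: _make_angled(
            True, _nondesens(), None, "angled_same_nondesens"
        ),
        "angled_diff_nondesens": lambda: _make_angled(
            False, _nondesens(), _nondesens(), "angled_diff_nondesens"
        ),
        "angled_mixed": lambda: _make_angled(False, _nondesens(), _desens(), "angled_mixed"),
        "nav_A": lambda: _make_nav("nav_A"),
        "nav_B": lambda: _make_nav("nav_B"),
        "nav_C": lambda: _make_nav("nav_C"),
        "nav_D": lambda: _make_nav("nav_D"),
        "orientmap_single": lambda: _make_orientmap("orientmap_single"),
        "orientmap_opposing": lambda: _make_orientmap("orientmap_opposing"),
    }
)


def list_scenarios() -> list[str]:
    """Names of all registered presets."""
    return sorted(_PRESETS)


def build_scenario(name: str, overrides: Optional[Mapping] = None) -> Scenario:
    """Build a named preset, optionally shallow-merging overrides.

    Overrides use the serialized-config structure, e.g.
    ``{"migration": {"seed": 7}}`` or ``{"starts": [[0, 0]]}``; nested
    dictionaries merge key-wise, everything else replaces.
    """
    if name not in _PRESETS:
        raise ScenarioNotFoundError(
            f"unknown scenario {name!r}; valid names: {', '.join(list_scenarios())}"
        )
    scenario = _PRESETS[name]()
    if not overrides:
        return scenario
    cfg = scenario_to_dict(scenario)
    for key, val in overrides.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return scenario_from_dict(cfg)


# ---------------------------------------------------------------------------
# serialization (single JSON/YAML document; um, min, nM, s^-1)

def scenario_to_dict(s: Scenario) -> dict:
    return {
        "name": s.name,
        "fields": [
            {
                "ligand": f.ligand_id,
                "center": list(f.center),
                "Lmax": f.L_max,
                "L0": f.L_0,
                "A": f.A,
                "n": f.n,
            }
            for f in s.env.fields
        ],
        "kinetics": {lig: asdict(p) for lig, p in s.params_by_ligand.items()},
        "geometry": {"unit_radius": s.geometry.unit_radius, "n_units": s.geometry.n_units},
        "starts": [list(p) for p in s.starts],
        "migration": asdict(s.migration),
    }


def scenario_from_dict(cfg: Mapping) -> Scenario:
    fields = [
        PowerGradientField(
            ligand_id=f["ligand"],
            center=tuple(f["center"]),
            L_max=f["Lmax"],
            L_0=f.get("L0", 0.0),
            A=f.get("A", 1000.0),
            n=f.get("n", 3.0),
        )
        for f in cfg.get("fields", [])
    ]
    params = {lig: KineticParams(**kv) for lig, kv in cfg.get("kinetics", {}).items()}
    geo = CellGeometry(**cfg.get("geometry", {}))
    return Scenario(
        name=cfg.get("name", "custom"),
        env=LigandEnvironment(fields),
        params_by_ligand=params,
        geometry=geo,
        starts=tuple(tuple(p) for p in cfg.get("starts", [])),
        migration=MigrationConfig(**cfg.get("migration", {})),
    )


def save_scenario(s: Scenario, path) -> None:
    """Write a scenario config as JSON or YAML (chosen by file suffix)."""
    path = Path(path)
    cfg = scenario_to_dict(s)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def load_scenario(path) -> Scenario:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    return scenario_from_dict(cfg)


# ---------------------------------------------------------------------------
# track metrics and CSV round trip

@dataclass(frozen=True)
class TrackMetrics:
    """Summary statistics of one track relative to a target source."""

    track_id: int
    path_length: float
    net_displacement: float
    chemotactic_index: float
    final_distance_to: dict[str, float]


def track_metrics(track: Track, scenario: Scenario, target: str) -> TrackMetrics:
    """Chemotactic index = net displacement projected onto the start->target
    direction, divided by total path length (in [-1, 1])."""
    sources = scenario.source_labels()
    if target not in sources:
        raise ParameterError(
            f"unknown target {target!r}; sources: {sorted(sources)}"
        )
    start = np.array([track.x[0], track.y[0]])
    end = track.final_position
    path = track.path_length
    disp = end - start
    to_target = np.asarray(sources[target], dtype=float) - start
    norm = np.linalg.norm(to_target)
    if path > 0 and norm > 0:
        ci = float(disp @ (to_target / norm)) / path
    else:
        ci = 0.0
    final_d = {
        lab: float(np.hypot(end[0] - c[0], end[1] - c[1])) for lab, c in sources.items()
    }
    return TrackMetrics(
        track_id=track.track_id,
        path_length=path,
        net_displacement=float(np.linalg.norm(disp)),
        chemotactic_index=ci,
        final_distance_to=final_d,
    )


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    frames = []
    for tr in tracks:
        df = tr.to_dataframe()
        df.insert(0, "track_id", tr.track_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_tracks_csv(tracks: list[Track], path) -> None:
    """One CSV per cohort: track_id,t_min,x_um,y_um,heading_rad,net_mag,mode."""
    tracks_to_dataframe(tracks).to_csv(path, index=False, float_format="%.8g")


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        out.append(
            Track(
                t=g["t_min"].to_numpy(float),
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
                heading=g["heading_rad"].to_numpy(float),
                net_mag=g["net_mag"].to_numpy(float),
                mode=g["mode"].to_numpy(object),
                track_id=int(tid),
            )
        )
    return out
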