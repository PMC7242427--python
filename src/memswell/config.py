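"""Configuration schema, fixtures, trajectory CSV writers and run manifests.

Configs are YAML (JSON is a subset and accepted) with every physical
quantity written as a ``"value unit"`` string — the unit ambiguity of
mixed CGS/SI membrane literature makes implicit units dangerous, so
units are explicit everywhere and converted on load.  Unknown keys are
rejected, defaults (temperature 310 K, energy-min partition, SI water
permeability) are applied, and errors name the offending key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import pydantic
import yaml

from . import __version__
from .dynamics import SimulationConfig, Trajectory
from .geometry import EllipsoidShape
from .mechanics import MediumState, RigidityTensorParams
from .units import UnitError, convert

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "make_fixtures",
    "write_trajectory",
    "read_trajectory",
    "EQUILIBRIUM_SHAPES",
]

#: reported equilibrium shapes of the swollen oblate cell per initial
#: NaCl concentration: (concentration mM, a um, c um)
EQUILIBRIUM_SHAPES: tuple[tuple[float, float, float], ...] = (
    (0.0, 8.00, 2.00),
    (10.0, 8.20, 2.06),
    (20.0, 8.32, 2.10),
    (30.0, 8.39, 2.13),
    (40.0, 8.47, 2.15),
    (50.0, 8.53, 2.17),
)

#: default water permeability, m s^-1 Pa^-1 — see docs/methods.md for the
#: reasoning behind this magnitude
DEFAULT_P_W = "3.1e-14 m/s/Pa"

#: stretch-rigidity preset of the inner-mitochondrial-membrane fit, with
#: the water permeability in its originally printed units
IMM_PRESET = {
    "g00": "0.0101 dyn/nm",
    "gzz0": "0.008 dyn/nm",
    "beta0": "1.8e4 um^-4",
    "betaz": "1.6e4 um^-4",
    "n1": 4,
}
IMM_P_W_AS_PRINTED = "3.1e2 ul/min/Pa/um^2"


class ConfigError(ValueError):
    """Configuration file is invalid; the message names the offending key."""


# ---------------------------------------------------------------------------
# schema (pydantic models validate structure; unit conversion happens after)


class _Strict(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class _ShapeModel(_Strict):
    a: str | float
    c: str | float


class _SpeciesModel(_Strict):
    inside: str | float
    outside: str | float


class _MediumModel(_Strict):
    temperature: str | float = "310 K"
    species: dict[str, _SpeciesModel]


class _RigidityModel(_Strict):
    g00: str | float = IMM_PRESET["g00"]
    gzz0: str | float = IMM_PRESET["gzz0"]
    beta0: str | float = IMM_PRESET["beta0"]
    betaz: str | float = IMM_PRESET["betaz"]
    n1: int = 4


class _SolverModel(_Strict):
    rtol: float = 1e-8
    atol: float = 1e-8


class _ConfigModel(_Strict):
    shape: _ShapeModel
    medium: _MediumModel
    rigidity: _RigidityModel = _RigidityModel()
    p_w: str | float = DEFAULT_P_W
    time_span: str | float = "2e6 s"
    solver: _SolverModel = _SolverModel()
    partition_rule: str = "energy-min"
    saturation_threshold: float = 1e-9
    n_output: int = 161
    seed: int | None = None


def _convert(key: str, raw, kind: str, **kw) -> float:
    try:
        return convert(raw, kind, **kw)
    except UnitError as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Load and fully resolve a simulation config (YAML or JSON)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        model = _ConfigModel.model_validate(raw)
    except pydantic.ValidationError as exc:
        err = exc.errors()[0]
        key = ".".join(str(p) for p in err["loc"])
        raise ConfigError(f"{key}: {err['msg']}") from exc

    a = _convert("shape.a", model.shape.a, "length")
    c = _convert("shape.c", model.shape.c, "length")
    if a <= 0:
        raise ConfigError("shape.a: semi-axis must be positive")
    if c <= 0:
        raise ConfigError("shape.c: semi-axis must be positive")
    shape = EllipsoidShape(a, c)

    if not model.medium.species:
        raise ConfigError("medium.species: at least one species required")
    table = {}
    for name, sp in model.medium.species.items():
        table[name] = (
            _convert(f"medium.species.{name}.inside", sp.inside, "concentration"),
            _convert(f"medium.species.{name}.outside", sp.outside, "concentration"),
        )
    T = _convert("medium.temperature", model.medium.temperature, "temperature")
    try:
        medium = MediumState.from_dict(table, T=T)
    except ValueError as exc:
        raise ConfigError(f"medium: {exc}") from exc

    r = model.rigidity
    try:
        rigidity = RigidityTensorParams(
            g00=_convert("rigidity.g00", r.g00, "rigidity"),
            gzz0=_convert("rigidity.gzz0", r.gzz0, "rigidity"),
            beta0=_convert("rigidity.beta0", r.beta0, "disruption", n1=r.n1),
            betaz=_convert("rigidity.betaz", r.betaz, "disruption", n1=r.n1),
            n1=r.n1,
        )
    except ValueError as exc:
        raise ConfigError(f"rigidity: {exc}") from exc

    try:
        return SimulationConfig(
            shape=shape,
            medium=medium,
            rigidity=rigidity,
            p_w=_convert("p_w", model.p_w, "permeability"),
            t_span=_convert("time_span", model.time_span, "time"),
            rtol=model.solver.rtol,
            atol=model.solver.atol,
            partition_rule=model.partition_rule,
            saturation_threshold=model.saturation_threshold,
            n_output=model.n_output,
            seed=model.seed,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# fixtures


def _scenario_dict(c_in_mM: float, p_w: str = DEFAULT_P_W) -> dict:
    return {
        "shape": {"a": "8 um", "c": "2 um"},
        "medium": {
            "temperature": "310 K",
            "species": {
                "Na": {"inside": f"{c_in_mM:g} mM", "outside": "1 mM"},
                "Cl": {"inside": f"{c_in_mM:g} mM", "outside": "1 mM"},
            },
        },
        "rigidity": dict(IMM_PRESET),
        "p_w": p_w,
        "time_span": "5e6 s",
    }


def make_fixtures(outdir: str | Path) -> list[Path]:
    """Write the named parameter presets and sweep scenarios.

    * ``imm_rigidity.yaml`` — the published rigidity-tensor preset with
      the water permeability in its originally printed (non-SI) units;
    * ``equilibrium_shapes.csv`` — the six reported equilibrium shapes
      (0–50 mM);
    * ``swell_<c>mM.yaml`` for c in 10..50 — sweep scenarios with the SI
      default permeability and 1 mM external NaCl.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = outdir / "imm_rigidity.yaml"
    p.write_text(
        yaml.safe_dump(
            _scenario_dict(50.0, p_w=IMM_P_W_AS_PRINTED), sort_keys=False
        )
    )
    written.append(p)

    p = outdir / "equilibrium_shapes.csv"
    df = pd.DataFrame(EQUILIBRIUM_SHAPES, columns=["concentration_mM", "a_um", "c_um"])
    df.to_csv(p, index=False, lineterminator="\n")
    written.append(p)

    for c in (10, 20, 30, 40, 50):
        p = outdir / f"swell_{c}mM.yaml"
        p.write_text(yaml.safe_dump(_scenario_dict(float(c)), sort_keys=False))
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# trajectory CSV, manifests


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """CSV with the fixed column set, 12 significant digits, LF endings."""
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    traj.to_frame().to_csv(
        path, index=False, float_format="%.12g", lineterminator="\n"
    )
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every CLI output set."""

    config_sha256: str
    fixtures: tuple[str, ...]
    rtol: float
    atol: float
    version: str
    started_utc: str

    @classmethod
    def for_run(
        cls, config_path: str | Path | None, config: SimulationConfig,
        fixtures: tuple[str, ...] = (),
    ) -> "RunManifest":
        if config_path is not None:
            digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        else:
            digest = hashlib.sha256(repr(config).encode()).hexdigest()
        return cls(
            config_sha256=digest,
            fixtures=fixtures,
            rtol=config.rtol,
            atol=config.atol,
            version=__version__,
            started_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path
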