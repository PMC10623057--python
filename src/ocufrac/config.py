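"""Study configuration: a small YAML schema with explicit physical units.

Every physical quantity in a config file is written as ``"value unit"``
(e.g. ``"2.2 mm"``, ``"9.82 MPa"``, ``"5.40 kJ/m^2"``) or as a bare number,
which is taken to be SI.  Values are converted to SI on load; the bundled
configs use finite decimals so the conversion is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .elasticity import Material
from .geometry import IncisionShape, PlateSpec
from .meshing import MeshParams

__all__ = ["StudyConfig", "ConfigError", "load_config", "parse_quantity"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


_UNITS = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "GPa": 1e9},
    "toughness": {"J/m^2": 1.0, "J/m2": 1.0, "kJ/m^2": 1e3, "kJ/m2": 1e3},
    "angle": {"deg": 1.0, "degree": 1.0, "degrees": 1.0},
    "dimensionless": {"": 1.0},
}


def parse_quantity(value, kind: str, where: str = "") -> float:
    """Convert ``"2.2 mm"`` (or a bare SI number) to an SI float."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2:
            try:
                mag = float(parts[0])
            except ValueError:
                raise ConfigError(f"{where}: cannot parse number in {value!r}") from None
            table = _UNITS[kind]
            if parts[1] not in table:
                raise ConfigError(
                    f"{where}: unknown {kind} unit {parts[1]!r} "
                    f"(expected one of {sorted(table)})"
                )
            return mag * table[parts[1]]
        try:
            return float(value)
        except ValueError:
            raise ConfigError(f"{where}: cannot parse quantity {value!r}") from None
    raise ConfigError(f"{where}: expected a number or 'value unit' string, got {value!r}")


@dataclass
class StudyConfig:
    """Fully resolved study description (all quantities SI)."""

    protocol: str  # calibrate | solve | sweep-chevron | sweep-frown |
    #               critical-length | orthotropy-table | compare
    plate: PlateSpec = field(default_factory=PlateSpec)
    shape: IncisionShape | None = None
    material: Material = field(default_factory=Material.isotropic)
    mesh: MeshParams = field(default_factory=MeshParams)
    d_target: float = 1.73e-3
    angles: list | None = None  # sweep grid [deg]
    refine: bool = True
    family: str = "straight"  # for critical-length
    angle: float | None = None
    bracket: tuple = (1.5e-3, 3.5e-3)
    etas: list | None = None
    sigma0: float | None = None  # fixed-load solve [Pa]
    output_dir: str = "ocufrac-out"


_PROTOCOLS = ("calibrate", "solve", "sweep-chevron", "sweep-frown",
              "critical-length", "orthotropy-table", "compare")

_TOP_KEYS = {"protocol", "plate", "shape", "material", "mesh", "d_target",
             "angles", "refine", "family", "angle", "bracket", "etas",
             "sigma0", "output_dir"}
_PLATE_KEYS = {"width", "height"}
_SHAPE_KEYS = {"family", "total_length", "alpha", "beta"}
_MAT_KEYS = {"kind", "E", "nu", "E_x", "E_y", "nu_xy", "G_xy", "G_c"}
_MESH_KEYS = {"n_rings", "r_inner", "ring_growth", "n_spokes", "far_field_size",
              "outer_growth", "n_blend", "crack_spacing_cap_frac"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    for k in d:
        if k not in allowed:
            raise ConfigError(f"{where}.{k}: unknown key")


def load_config(path) -> StudyConfig:
    """Parse and validate a YAML study config into SI quantities."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    if "protocol" not in raw:
        raise ConfigError("config.protocol: required")
    protocol = raw["protocol"]
    if protocol not in _PROTOCOLS:
        raise ConfigError(f"config.protocol: unknown protocol {protocol!r} "
                          f"(expected one of {_PROTOCOLS})")

    cfg = StudyConfig(protocol=protocol)

    if "plate" in raw:
        p = raw["plate"] or {}
        _check_keys(p, _PLATE_KEYS, "plate")
        cfg.plate = PlateSpec(
            width=parse_quantity(p.get("width", 0.060), "length", "plate.width"),
            height=parse_quantity(p.get("height", 0.060), "length", "plate.height"),
        )
    if "shape" in raw:
        s = raw["shape"] or {}
        _check_keys(s, _SHAPE_KEYS, "shape")
        family = s.get("family", "straight")
        a = parse_quantity(s.get("total_length", "2.2 mm"), "length",
                           "shape.total_length") / 2.0
        if family == "straight":
            cfg.shape = IncisionShape.straight(a)
        elif family == "chevron":
            if "alpha" not in s:
                raise ConfigError("shape.alpha: required for a chevron incision")
            cfg.shape = IncisionShape.chevron(
                a, parse_quantity(s["alpha"], "angle", "shape.alpha"))
        elif family == "frown":
            if "beta" not in s:
                raise ConfigError("shape.beta: required for a frown incision")
            cfg.shape = IncisionShape.frown(
                a, parse_quantity(s["beta"], "angle", "shape.beta"))
        else:
            raise ConfigError(f"shape.family: unknown family {family!r}")
    if "material" in raw:
        m = raw["material"] or {}
        _check_keys(m, _MAT_KEYS, "material")
        kind = m.get("kind", "isotropic")
        G_c = parse_quantity(m.get("G_c", "5.40 kJ/m^2"), "toughness", "material.G_c")
        if kind == "isotropic":
            cfg.material = Material.isotropic(
                E=parse_quantity(m.get("E", "9.82 MPa"), "pressure", "material.E"),
                nu=parse_quantity(m.get("nu", 0.49), "dimensionless", "material.nu"),
                G_c=G_c,
            )
        elif kind == "orthotropic":
            for req in ("E_x", "E_y"):
                if req not in m:
                    raise ConfigError(f"material.{req}: required for orthotropic")
            cfg.material = Material.orthotropic(
                E_x=parse_quantity(m["E_x"], "pressure", "material.E_x"),
                E_y=parse_quantity(m["E_y"], "pressure", "material.E_y"),
                nu_xy=(parse_quantity(m["nu_xy"], "dimensionless", "material.nu_xy")
                       if "nu_xy" in m else None),
                G_xy=(parse_quantity(m["G_xy"], "pressure", "material.G_xy")
                      if "G_xy" in m else None),
                nu=parse_quantity(m.get("nu", 0.49), "dimensionless", "material.nu"),
                G_c=G_c,
            )
        else:
            raise ConfigError(f"material.kind: unknown kind {kind!r}")
    if "mesh" in raw:
        me = raw["mesh"] or {}
        _check_keys(me, _MESH_KEYS, "mesh")
        kwargs = {}
        for key in ("n_rings", "n_spokes", "n_blend"):
            if key in me:
                kwargs[key] = int(me[key])
        for key in ("ring_growth", "outer_growth", "crack_spacing_cap_frac"):
            if key in me:
                kwargs[key] = parse_quantity(me[key], "dimensionless", f"mesh.{key}")
        for key in ("r_inner", "far_field_size"):
            if key in me:
                kwargs[key] = parse_quantity(me[key], "length", f"mesh.{key}")
        cfg.mesh = MeshParams(**kwargs)

    if "d_target" in raw:
        cfg.d_target = parse_quantity(raw["d_target"], "length", "d_target")
    if "sigma0" in raw:
        cfg.sigma0 = parse_quantity(raw["sigma0"], "pressure", "sigma0")
    if "angles" in raw:
        cfg.angles = [parse_quantity(x, "angle", "angles") for x in raw["angles"]]
    if "etas" in raw:
        cfg.etas = [float(x) for x in raw["etas"]]
    if "refine" in raw:
        cfg.refine = bool(raw["refine"])
    if "family" in raw:
        cfg.family = str(raw["family"])
    if "angle" in raw and raw["angle"] is not None:
        cfg.angle = parse_quantity(raw["angle"], "angle", "angle")
    if "bracket" in raw:
        b = raw["bracket"]
        if not (isinstance(b, (list, tuple)) and len(b) == 2):
            raise ConfigError("bracket: expected a 2-element list")
        cfg.bracket = tuple(parse_quantity(x, "length", "bracket") for x in b)
    if "output_dir" in raw:
        cfg.output_dir = str(raw["output_dir"])
    return cfg
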