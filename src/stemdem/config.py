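"""YAML run configuration: one file describes a complete, reproducible run.

A config bundles stem geometry, material/contact/bond parameters, the
integration settings and a load case.  Loading validates the schema
(unknown keys are rejected by name, physical invariants are enforced by the
parameter dataclasses) and fills documented defaults; a serialised copy of
the effective config is echoed into every output directory so a run can be
reproduced bit-identically for its deterministic stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import (
    BRANCH,
    CONTACT_PP,
    CONTACT_PW,
    CALIBRATED_OPTIMUM_BOND,
    STEEL,
    BondParams,
    ContactParams,
    MaterialParams,
    SimConfig,
)
from .loading import LoadCase

__all__ = ["StemGeometry", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class StemGeometry:
    """Cylindrical specimen geometry, mm."""

    diameter_mm: float = 9.3
    length_mm: float = 20.0
    particle_radius_mm: float = 0.5

    def __post_init__(self):
        if min(self.diameter_mm, self.length_mm, self.particle_radius_mm) <= 0:
            raise ValueError("geometry values must be positive")


@dataclass
class RunConfig:
    """Complete description of one simulation run."""

    stem: StemGeometry = field(default_factory=StemGeometry)
    bond: BondParams = field(default_factory=lambda: CALIBRATED_OPTIMUM_BOND)
    material: MaterialParams = field(default_factory=lambda: BRANCH)
    tool_material: MaterialParams = field(default_factory=lambda: STEEL)
    contact_pp: ContactParams = field(default_factory=lambda: CONTACT_PP)
    contact_pw: ContactParams = field(default_factory=lambda: CONTACT_PW)
    sim: SimConfig = field(default_factory=SimConfig)
    load: LoadCase = field(default_factory=lambda: LoadCase.compression())
    output_dir: str = "."
    seed: int = 0


_SECTIONS = {
    "stem": StemGeometry,
    "bond": BondParams,
    "material": MaterialParams,
    "tool_material": MaterialParams,
    "contact_pp": ContactParams,
    "contact_pw": ContactParams,
    "sim": SimConfig,
    "load": LoadCase,
}


def _build_section(name: str, cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {name!r}; "
            f"allowed: {sorted(fields)}"
        )
    coerced = {}
    for key, value in data.items():
        # YAML 1.1 reads bare scientific notation like 1e10 as a string
        if isinstance(value, str):
            try:
                value = float(value)
            except ValueError:
                pass
        coerced[key] = value
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    allowed = set(_SECTIONS) | {"output_dir", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(name, cls, section)
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    """Serialise a run configuration to YAML (round-trips with load)."""
    out = {}
    for name in _SECTIONS:
        out[name] = dataclasses.asdict(getattr(cfg, name))
    out["output_dir"] = cfg.output_dir
    out["seed"] = cfg.seed
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
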