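"""YAML run configuration: one mapping section per parameter group.

Example::

    geometry:   {radius: 0.010, artery_length: 0.200, micro_length: 0.100}
    waveform:   {period: 0.8, peak_velocity: 0.75}
    rheology:   {eta_inf: 2.2e-3, eta_0: 22.0e-3}
    porous:     {porosity: 0.5, microvessel_diameter: 8.0e-6, area_expansion: 1.0}
    wall:       {youngs_modulus: 5.0e6, rigid: false}
    solver:     {dt: 4.0e-3, residual_tol: 1.0e-4}
    coupling:   {cycles: 3, analysis_cycle: 3}
    resolution: {nz: 150, nr: 24}

Unknown keys raise immediately; omitted keys take the defaults above.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .constitutive import PorousParams, RheologyParams
from .driver import CouplingConfig
from .fluid import SolverConfig
from .geometry import GeometryConfig
from .wall import WallParams
from .waveform import WaveformConfig

__all__ = ["RunConfig", "load_config", "dump_config"]

_GROUPS = {
    "geometry": GeometryConfig,
    "waveform": WaveformConfig,
    "rheology": RheologyParams,
    "porous": PorousParams,
    "wall": WallParams,
    "solver": SolverConfig,
    "coupling": CouplingConfig,
}


@dataclasses.dataclass
class RunConfig:
    geometry: GeometryConfig = dataclasses.field(default_factory=GeometryConfig)
    waveform: WaveformConfig = dataclasses.field(default_factory=WaveformConfig)
    rheology: RheologyParams = dataclasses.field(default_factory=RheologyParams)
    porous: PorousParams = dataclasses.field(default_factory=PorousParams)
    wall: WallParams = dataclasses.field(default_factory=WallParams)
    solver: SolverConfig = dataclasses.field(default_factory=SolverConfig)
    coupling: CouplingConfig = dataclasses.field(default_factory=CouplingConfig)
    nz: int = 150
    nr: int = 24

    def run_kwargs(self) -> dict:
        return {
            "geometry": self.geometry,
            "waveform_config": self.waveform,
            "rheology": self.rheology,
            "porous": self.porous,
            "wall_params": self.wall,
            "solver": self.solver,
            "coupling": self.coupling,
            "nz": self.nz,
            "nr": self.nr,
        }


def _build(cls, mapping, group):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config group '{group}'")
    if "section_fractions" in mapping:
        mapping = dict(mapping, section_fractions=tuple(mapping["section_fractions"]))
    return cls(**mapping)


def load_config(path_or_mapping) -> RunConfig:
    """Build a RunConfig from a YAML file path or an already-parsed mapping."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_mapping or {})
    known = set(_GROUPS) | {"resolution"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config group(s): {sorted(unknown)}")
    kwargs = {}
    for group, cls in _GROUPS.items():
        kwargs[group] = _build(cls, data.get(group) or {}, group)
    res = data.get("resolution") or {}
    extra = set(res) - {"nz", "nr"}
    if extra:
        raise ValueError(f"unknown key(s) {sorted(extra)} in config group 'resolution'")
    return RunConfig(nz=int(res.get("nz", 150)), nr=int(res.get("nr", 24)), **kwargs)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialise a RunConfig back to YAML (the provenance echo of a run)."""
    data = {}
    for group in _GROUPS:
        obj = getattr(config, group)
        d = dataclasses.asdict(obj)
        if "section_fractions" in d:
            d["section_fractions"] = list(d["section_fractions"])
        data[group] = d
    data["resolution"] = {"nz": config.nz, "nr": config.nr}
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
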