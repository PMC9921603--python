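"""Pipeline configuration: nested sections, YAML round-trip, strict keys.

Defaults are the published processing constants: bandpass 10--500 Hz, notch
48--52 Hz, activation shape A = -20, GA population 20 / crossover 0.7 /
2 elites / stall 1e-6 over 20 generations, RLS prior P0 = 0.01*I.
Unknown keys in a loaded file raise a :class:`SchemaError`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import SchemaError

__all__ = ["PipelineConfig", "EMGSection", "ActivationSection", "SimSection",
           "GASection", "RLSSection", "ScalesSection", "IOSection"]


@dataclass
class EMGSection:
    bandpass: list = field(default_factory=lambda: [10.0, 500.0])
    notch: list = field(default_factory=lambda: [48.0, 52.0])
    order: int = 5
    envelope_cutoff: float = 6.0
    input_kind: str = "envelope"   # "raw" | "envelope"


@dataclass
class ActivationSection:
    A: float = -20.0


@dataclass
class SimSection:
    dt: float = 5e-4
    integrator: str = "rk4"
    gravity_mode: str = "paper"
    sign_convention: str = "flexion_positive"
    q_guard: float = float(np.pi)
    fiber_init: str = "optimal"


@dataclass
class GASection:
    population_size: int = 20
    crossover_fraction: float = 0.7
    elite_count: int = 2
    mutation_rate: float = 1.0
    mutation_sigma: float = 0.1
    stall_tol: float = 1e-6
    stall_generations: int = 20
    max_generations: int = 200
    seed: int = 0
    bounds_preset: str = "table"


@dataclass
class RLSSection:
    n_terms: int = 3
    p0: float = 0.01
    forgetting: float = 1.0
    mode: str = "derivative"   # | "paper_literal"


@dataclass
class ScalesSection:
    phase_points: int = 101
    statistic: str = "area"        # | "mean"
    aggregate: str = "mean"        # | "median"
    full_range_deg: float = 150.0


@dataclass
class IOSection:
    angle_unit: str = "deg"
    mvc_agonist: float = 1.0
    mvc_antagonist: float = 1.0


_SECTIONS = {
    "emg": EMGSection,
    "activation": ActivationSection,
    "sim": SimSection,
    "ga": GASection,
    "rls": RLSSection,
    "scales": ScalesSection,
    "io": IOSection,
}


@dataclass
class PipelineConfig:
    emg: EMGSection = field(default_factory=EMGSection)
    activation: ActivationSection = field(default_factory=ActivationSection)
    sim: SimSection = field(default_factory=SimSection)
    ga: GASection = field(default_factory=GASection)
    rls: RLSSection = field(default_factory=RLSSection)
    scales: ScalesSection = field(default_factory=ScalesSection)
    io: IOSection = field(default_factory=IOSection)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(_SECTIONS)
        if unknown:
            raise SchemaError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            sub = d.get(name, {})
            allowed = {f.name for f in fields(section_cls)}
            bad = set(sub) - allowed
            if bad:
                raise SchemaError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
            kwargs[name] = section_cls(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise SchemaError("config file must contain a mapping")
        return cls.from_dict(data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def sim_config(self):
        from .dynamics import SimConfig

        return SimConfig(dt=self.sim.dt, integrator=self.sim.integrator,
                         gravity_mode=self.sim.gravity_mode,
                         sign_convention=self.sim.sign_convention,
                         q_guard=self.sim.q_guard, fiber_init=self.sim.fiber_init)

    def ga_config(self):
        from .ga import GAConfig

        g = self.ga
        return GAConfig(population_size=g.population_size,
                        crossover_fraction=g.crossover_fraction,
                        elite_count=g.elite_count, mutation_rate=g.mutation_rate,
                        mutation_sigma=g.mutation_sigma, stall_tol=g.stall_tol,
                        stall_generations=g.stall_generations,
                        max_generations=g.max_generations, seed=g.seed)
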