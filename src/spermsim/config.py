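"""Run configuration: all model and experiment parameters in one place.

A :class:`SimulationConfig` fully determines a cohort run, including the
species preset (sea urchin: continuous desensitization, 300,000 initial GC;
starfish: turn-triggered desensitization, 110,000 initial GC), the field
geometry, the master seed, and the optional egg-position disturbance.
Configurations round-trip through plain dicts / YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .gradient import PM, RadialField, solve_field
from .motility import SEA_URCHIN_TURN, STARFISH_TURN, TurnProfile
from .signaling import CONTINUOUS, TURN_TRIGGERED, BindingParams

__all__ = ["DisturbanceParams", "FieldParams", "SimulationConfig"]

SEA_URCHIN = "sea_urchin"
STARFISH = "starfish"

FRAME_DT = 0.060  # s; the model's unit time


@dataclass(frozen=True)
class FieldParams:
    """Chemoattractant field geometry; surface concentration in pM at this
    interface (stored internally in nM by :class:`~spermsim.gradient.RadialField`)."""

    egg_radius: float = 100.0          # μm, including the egg coat
    field_radius: float = 5000.0       # μm
    surface_concentration_pM: float = 100.0

    def solve(self) -> RadialField:
        return solve_field(self.egg_radius, self.field_radius,
                           self.surface_concentration_pM * PM)


@dataclass(frozen=True)
class DisturbanceParams:
    """Sine-wave oscillation of the egg position along the y-axis."""

    enabled: bool = False
    amplitude: float = 500.0   # μm
    frequency: float = 0.01    # Hz

    def __post_init__(self) -> None:
        if self.enabled:
            if self.amplitude < 0:
                raise ValueError("disturbance amplitude must be non-negative")
            if not self.frequency > 0:
                raise ValueError("disturbance frequency must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one cohort simulation."""

    species: str = SEA_URCHIN
    start_distance: float = 2000.0      # μm from egg center
    duration_frames: int = 30_000       # 30 min at 60 ms per frame
    n_sperm: int = 10_000
    seed: int = 0
    freeze_desensitization: bool = False
    fixed_phase: bool = False           # start all agents at the same circle phase
    dt: float = FRAME_DT
    speed: float = 150.0                # μm/s
    circling_radius: float = 25.0       # μm
    clockwise: bool = True
    field: FieldParams = dataclasses.field(default_factory=FieldParams)
    binding: BindingParams = dataclasses.field(default_factory=BindingParams)
    turn_profile: TurnProfile = SEA_URCHIN_TURN
    disturbance: DisturbanceParams = dataclasses.field(default_factory=DisturbanceParams)

    def __post_init__(self) -> None:
        if self.species not in (SEA_URCHIN, STARFISH):
            raise ValueError(f"unknown species {self.species!r}")
        if not 0 < self.start_distance <= self.field.field_radius:
            raise ValueError("start_distance must lie within the field")
        if self.duration_frames < 0 or self.n_sperm < 0:
            raise ValueError("duration_frames and n_sperm must be non-negative")
        if not (self.speed > 0 and self.circling_radius > 0):
            raise ValueError("speed and circling_radius must be positive")

    # -- species presets ---------------------------------------------------

    @classmethod
    def sea_urchin(cls, **overrides) -> "SimulationConfig":
        """Sea urchin preset: continuous (time-based) desensitization."""
        binding = overrides.pop("binding", BindingParams(initial_gc=300_000))
        profile = overrides.pop("turn_profile", SEA_URCHIN_TURN)
        return cls(species=SEA_URCHIN, binding=binding, turn_profile=profile,
                   **overrides)

    @classmethod
    def starfish(cls, **overrides) -> "SimulationConfig":
        """Starfish preset: discrete (turn-triggered) desensitization."""
        binding = overrides.pop("binding", BindingParams(initial_gc=110_000))
        profile = overrides.pop("turn_profile", STARFISH_TURN)
        return cls(species=STARFISH, binding=binding, turn_profile=profile,
                   **overrides)

    @classmethod
    def for_species(cls, species: str, **overrides) -> "SimulationConfig":
        if species == SEA_URCHIN:
            return cls.sea_urchin(**overrides)
        if species == STARFISH:
            return cls.starfish(**overrides)
        raise ValueError(f"unknown species {species!r}")

    # -- derived quantities ------------------------------------------------

    @property
    def scheme(self) -> str:
        return CONTINUOUS if self.species == SEA_URCHIN else TURN_TRIGGERED

    @property
    def baseline_curvature(self) -> float:
        """Signed baseline curvature, 1/μm (negative = clockwise)."""
        k = 1.0 / self.circling_radius
        return -k if self.clockwise else k

    @property
    def duration_seconds(self) -> float:
        return self.duration_frames * self.dt

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["turn_profile"] = {
            "multipliers": list(self.turn_profile.multipliers),
            "refractory_frames": self.turn_profile.refractory_frames,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "field" in d:
            d["field"] = FieldParams(**d["field"])
        if "binding" in d:
            d["binding"] = BindingParams(**d["binding"])
        if "disturbance" in d:
            d["disturbance"] = DisturbanceParams(**d["disturbance"])
        if "turn_profile" in d:
            d["turn_profile"] = TurnProfile(**d["turn_profile"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
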