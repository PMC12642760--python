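"""Arena configuration.

One flat dataclass carries everything the simulator, field model and sensor
bank need: geometry, kinematic limits, food dynamics, reward constants,
electric-field constants and sensor layout.  Units are centimetres, seconds
and radians throughout; field strengths are in arbitrary units (only ratios
reach the policy).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["ArenaConfig", "load_arena_yaml"]


@dataclass
class ArenaConfig:
    # geometry / episode
    width_cm: float = 200.0
    height_cm: float = 200.0
    dt_s: float = 0.04           # 25 Hz; a 0.36 s analysis window is exactly 9 steps
    max_steps: int = 1500        # 60 s episodes
    n_agents: int = 4
    seed: int = 0
    scenario: str = "default"    # "default" | "two_fish" (special placement at reset)

    # food
    n_patches: int = 3
    patch_radius_cm: float = 10.0
    patch_capacity: int = 5
    replenish_rate_per_s: float = 0.2
    competition: bool = True     # False => patches instantly refilled to capacity

    # kinematics
    v_max_cm_s: float = 20.0
    omega_max_rad_s: float = math.pi
    eat_radius_cm: float = 2.0
    bite_radius_cm: float = 4.0

    # rewards
    r_food: float = 1.0
    c_eod: float = 0.01          # energetic cost per discharge
    c_bite: float = 1.0          # scale of the bite penalty
    bite_k: float = 6.0          # logistic steepness on dominance difference

    # electric field
    emitter_amplitude: float = 100.0
    alpha_food: float = 100.0    # polarizability of a food item
    alpha_body: float = 200.0    # polarizability of a conspecific body
    passive_moment: float = 5.0  # static (prey bioelectric) dipole strength
    kappa: float = 1.0
    r_min_cm: float = 1.0        # softening radius of the dipole law
    reflections_enabled: bool = True  # first-order wall images ("tank" vs open water)

    # sensors
    n_receptors: int = 8
    n_bins: int = 8              # Knollenorgan angular bins
    body_semi_major_cm: float = 3.0
    body_semi_minor_cm: float = 1.0
    knollenorgan_a0: float = 100.0
    knollenorgan_enabled: bool = True
    collective_sensing_enabled: bool = True
    comm_radius_cm: float = 50.0
    log_scale: float = 1.0       # signed-log compression scale, per block
    sensor_noise_std: float = 0.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.dt_s <= 0 or self.max_steps <= 0:
            raise ValueError("dt_s and max_steps must be positive")
        if self.n_agents < 1:
            raise ValueError("need at least one agent")
        if self.replenish_rate_per_s < 0:
            raise ValueError("replenish_rate_per_s must be >= 0")
        if self.patch_capacity < 1:
            raise ValueError("patch_capacity must be >= 1")
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")
        if 2 * self.patch_radius_cm > min(self.width_cm, self.height_cm):
            raise ValueError("patch does not fit inside the arena")
        if self.n_receptors < 1 or self.n_bins < 1:
            raise ValueError("n_receptors and n_bins must be >= 1")
        if self.r_min_cm <= 0:
            raise ValueError("r_min_cm must be positive")
        if self.scenario not in ("default", "two_fish"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "two_fish" and (self.n_agents != 2 or self.n_patches != 1):
            raise ValueError("two_fish scenario requires n_agents=2 and n_patches=1")

    @property
    def obs_dim(self) -> int:
        """active + passive + knollenorgan + (speed, last turn, own eod)."""
        return 2 * self.n_receptors + self.n_bins + 3

    def replace(self, **overrides: Any) -> "ArenaConfig":
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown ArenaConfig keys: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ArenaConfig keys: {sorted(unknown)}")
        return cls(**d)


def load_arena_yaml(path: str) -> ArenaConfig:
    """Load an ArenaConfig from a flat YAML document; unknown keys rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("arena config YAML must be a mapping")
    return ArenaConfig.from_dict(doc)
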