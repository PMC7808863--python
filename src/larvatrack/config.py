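"""Declarative YAML configuration for simulations and analysis defaults.

A config file holds the arena geometry, one behaviour block per group,
render parameters and seeds, e.g.::

    arena:
      width_px: 520
      height_px: 400
      dish_center: [260, 200]
      dish_radius_px: 190
      food_center: [205, 160]
      food_radius_px: 25
      frame_interval_s: 3
    behavior:
      mock: {step_mean_px: 3.0}
      infected: {step_mean_px: 6.0, bout_duration_mean_s: 600.0,
                 mode: edge_following, mode_switch_h: 9.0}
    render: {noise_sd: 2.0}
    seed: 1
    duration_h: 24

Omitted keys fall back to package defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .arena import ArenaSpec
from .synthetic import BehaviorParams, RenderParams


@dataclass
class SimulationConfig:
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    behavior: dict[str, BehaviorParams] = field(default_factory=dict)
    render: RenderParams = field(default_factory=RenderParams)
    seed: int = 0
    duration_h: float = 24.0


def _tupleize(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: (tuple(v) if k in keys else v) for k, v in d.items()}


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    arena = ArenaSpec(**_tupleize(raw.get("arena", {}), ("dish_center", "food_center")))
    behavior = {
        name: BehaviorParams(**block)
        for name, block in (raw.get("behavior") or {}).items()
    }
    render = RenderParams(**_tupleize(raw.get("render", {}), ("larva_axis_px",)))
    return SimulationConfig(
        arena=arena,
        behavior=behavior,
        render=render,
        seed=int(raw.get("seed", 0)),
        duration_h=float(raw.get("duration_h", 24.0)),
    )


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    raw = {
        "arena": {
            **asdict(cfg.arena),
            "dish_center": list(cfg.arena.dish_center),
            "food_center": list(cfg.arena.food_center),
        },
        "behavior": {name: asdict(p) for name, p in cfg.behavior.items()},
        "render": {
            **asdict(cfg.render),
            "larva_axis_px": list(cfg.render.larva_axis_px),
        },
        "seed": cfg.seed,
        "duration_h": cfg.duration_h,
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
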