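"""Microenvironment: immune killer agents and hypoxic overcrowding.

A single killer archetype merges the tumour-surveillance roles of NK cells
and macrophages: agents spawn (at ``immune_spawn_rate`` per tick) while any
spot's epithelial occupancy reaches ``immune_threshold``, patrol the lattice
by random walk, chase the nearest neoplastic cell within a Chebyshev
detection radius, and kill one neoplastic co-occupant per tick until a finite
kill budget is spent, at which point the agent expires.

Overcrowding mimics hypoxic niches: any spot holding more than
``hypoxia_threshold`` epithelial cells loses the excess occupants, chosen
uniformly.  Immune agents occupy spots but never count toward epithelial
crowding thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crypt_world import CryptGrid
from .genome import Typology

__all__ = [
    "ImmuneCell",
    "EnvConfig",
    "immune_trigger",
    "immune_step",
    "spawn_immune",
    "hypoxia_cull",
]


@dataclass
class EnvConfig:
    """Microenvironment thresholds and rates (all per spot / per tick)."""

    immune_threshold: int = 5
    hypoxia_threshold: int = 5
    immune_spawn_rate: int = 1
    immune_kill_budget: int = 5
    detection_radius: int = 3

    def __post_init__(self) -> None:
        for name in (
            "immune_threshold",
            "hypoxia_threshold",
            "immune_spawn_rate",
            "immune_kill_budget",
            "detection_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class ImmuneCell:
    """Patrolling killer agent with a finite kill budget."""

    __slots__ = ("id", "layer", "col", "kills_remaining")

    def __init__(self, agent_id: int, layer: int, col: int, kills_remaining: int = 5):
        self.id = agent_id
        self.layer = layer
        self.col = col
        self.kills_remaining = kills_remaining

    @property
    def pos(self) -> tuple:
        return (self.layer, self.col)


def immune_trigger(grid: CryptGrid, cfg: EnvConfig) -> bool:
    """True when any spot's epithelial occupancy reaches the immune threshold."""
    return grid.max_spot_count() >= cfg.immune_threshold


def _neoplastic_at(grid: CryptGrid, pos) -> list:
    return [c for c in grid.cells_at(pos) if c.typology.neoplastic]


def _nearest_neoplastic_spots(agent: ImmuneCell, grid: CryptGrid, radius: int):
    """Spots holding neoplastic cells at minimal positive Chebyshev distance."""
    best_d = None
    best = []
    for dl in range(-radius, radius + 1):
        layer = agent.layer + dl
        if not 0 <= layer < grid.n_layers:
            continue
        for dc in range(-radius, radius + 1):
            if dl == 0 and dc == 0:
                continue
            col = grid.wrap_col(agent.col + dc)
            if not _neoplastic_at(grid, (layer, col)):
                continue
            d = max(abs(dl), abs(dc))
            if best_d is None or d < best_d:
                best_d = d
                best = [(layer, col)]
            elif d == best_d:
                best.append((layer, col))
    return best


def _step_toward(agent: ImmuneCell, grid: CryptGrid, target) -> None:
    tl, tc = target
    dl = (tl > agent.layer) - (tl < agent.layer)
    dc_raw = (tc - agent.col) % grid.n_cols
    if dc_raw == 0:
        dc = 0
    elif dc_raw <= grid.n_cols - dc_raw:
        dc = 1
    else:
        dc = -1
    agent.layer += dl
    agent.col = grid.wrap_col(agent.col + dc)


def _step_random(agent: ImmuneCell, grid: CryptGrid, rng) -> None:
    dl, dc = (
        (0, -1),
        (0, 1),
        (1, 0),
        (-1, 0),
        (1, -1),
        (1, 1),
        (-1, -1),
        (-1, 1),
    )[rng.randrange(8)]
    nl = agent.layer + dl
    if 0 <= nl < grid.n_layers:
        agent.layer = nl
    agent.col = grid.wrap_col(agent.col + dc)


def immune_step(agent: ImmuneCell, grid: CryptGrid, cfg: EnvConfig, rng):
    """One tick of one immune agent.

    If a neoplastic cell shares the agent's spot it is killed outright;
    otherwise the agent moves one spot toward the nearest neoplastic cell
    within the detection radius (ties uniform), or one random spot if none is
    detected, and kills on arrival if it now co-occupies with prey.  At most
    one kill per tick; the kill budget is decremented here and the caller
    retires the agent when it hits zero.

    Returns ``("killed", cell)`` or ``("moved", None)``.
    """
    prey = _neoplastic_at(grid, agent.pos)
    if not prey:
        targets = _nearest_neoplastic_spots(agent, grid, cfg.detection_radius)
        if targets:
            _step_toward(agent, grid, targets[rng.randrange(len(targets))])
        else:
            _step_random(agent, grid, rng)
        prey = _neoplastic_at(grid, agent.pos)
    if prey:
        victim = prey[rng.randrange(len(prey))]
        agent.kills_remaining -= 1
        return ("killed", victim)
    return ("moved", None)


def spawn_immune(grid: CryptGrid, cfg: EnvConfig, rng, next_id) -> list:
    """Spawn agents at uniform random spots while the trigger condition holds."""
    if not immune_trigger(grid, cfg):
        return []
    agents = []
    for _ in range(cfg.immune_spawn_rate):
        layer = rng.randrange(grid.n_layers)
        col = rng.randrange(grid.n_cols)
        agents.append(ImmuneCell(next_id(), layer, col, cfg.immune_kill_budget))
    return agents


def hypoxia_cull(grid: CryptGrid, cfg: EnvConfig, rng) -> list:
    """Cells to die of overcrowding: the uniform excess over the threshold.

    A spot holding exactly the threshold loses nobody (the threshold is the
    maximum *allowed*).  Physiological occupants of an overcrowded spot are
    eligible victims like any other.
    """
    victims = []
    thr = cfg.hypoxia_threshold
    for pos, occupants in grid.iter_spots():
        excess = len(occupants) - thr
        if excess > 0:
            victims.extend(rng.sample(occupants, excess))
    return victims
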