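"""Tick loop, scenario configuration, stop conditions, seeded RNG.

One tick is one hour.  Each tick executes, in order:

1. every epithelial cell, in a freshly shuffled order: aging and death
   checks, differentiation, movement (exits at the crypt mouth), mitosis
   clock decrement and scheduled division; cells whose advance was blocked
   complete their single one-layer move once the blocker has moved on, so
   the epithelial column migrates one layer per hour as a whole;
2. gap-filling forced divisions;
3. hypoxic culling of overcrowded spots;
4. immune-agent spawning and stepping (shuffled);
5. stem-niche replenishment of base spots vacated during the hour (fresh
   transit-amplifying cells drawn from the initial-genotype distribution);
6. observer recording.

Runs stop when one model year has elapsed, when the transit-amplifying /
differentiated proportion inverts, or when the crypt population reaches the
population cap — whichever fires first.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cell_dynamics import (
    Cell,
    MitosisSchedule,
    StepContext,
    age_and_check_death,
    attempt_scheduled_mitosis,
    differentiate,
    gap_fill,
    move,
    sample_lifespan,
    try_advance,
)
from .crypt_world import CryptGrid
from .genome import (
    MutationModel,
    Typology,
    sample_initial_genotype,
)
from .microenvironment import (
    EnvConfig,
    hypoxia_cull,
    immune_step,
    spawn_immune,
)
from .observers import Metrics

__all__ = [
    "StopConfig",
    "SimConfig",
    "SimState",
    "RunResult",
    "initialize",
    "step",
    "check_stop",
    "run",
    "run_sweep",
    "SCENARIO_PROBS",
]

# the seven mutation-probability scenarios of the sweep
SCENARIO_PROBS = (1e-9, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)

#: ticks per model year in the standard scenario presets
MODEL_YEAR_TICKS = 365


@dataclass
class StopConfig:
    """Stop conditions: a year of ticks, proportion inversion, population cap."""

    max_ticks: int = 8760
    pop_cap: int = 10000
    proportion_inversion: bool = True

    def __post_init__(self) -> None:
        if self.max_ticks < 1 or self.pop_cap < 1:
            raise ValueError("max_ticks and pop_cap must be positive")


@dataclass
class SimConfig:
    """Full scenario configuration for one run.

    Defaults reproduce the reference physiological crypt: a 100x25 spot
    lattice, per-allele mutation probability ``base_prob``, initial driver
    heterozygosity ``p_het`` = 0.5, immune/hypoxia thresholds of 5 cells per
    spot, one immune agent spawned per hour while triggered, kill budget 5.
    """

    n_layers: int = 100
    n_cols: int = 25
    base_prob: float = 1e-9
    p_het: float = 0.5
    loh_factor: float = 10.0
    tp53_exponent_step: float = 0.5
    reg_threshold: int = 25
    p_slow: float = 0.25
    theta_diff: float = 0.75
    gap_fill_resets_clock: bool = True
    schedule: MitosisSchedule = field(default_factory=MitosisSchedule)
    env: EnvConfig = field(default_factory=EnvConfig)
    stop: StopConfig = field(default_factory=StopConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_prob", "p_het", "p_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.theta_diff <= 1.0:
            raise ValueError(f"theta_diff must be in (0, 1], got {self.theta_diff}")
        if self.n_layers < 2 or self.n_cols < 1:
            raise ValueError("n_layers must be >= 2 and n_cols >= 1")
        # delegate range checks on the genetic parameters
        self.mutation_model()

    def mutation_model(self) -> MutationModel:
        return MutationModel(
            base_prob=self.base_prob,
            loh_factor=self.loh_factor,
            tp53_exponent_step=self.tp53_exponent_step,
            reg_threshold=self.reg_threshold,
        )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "schedule" in data and isinstance(data["schedule"], dict):
            data["schedule"] = MitosisSchedule(**data["schedule"])
        if "env" in data and isinstance(data["env"], dict):
            data["env"] = EnvConfig(**data["env"])
        if "stop" in data and isinstance(data["stop"], dict):
            data["stop"] = StopConfig(**data["stop"])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "SimConfig":
        if str(path).endswith((".toml", ".tml")):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        return cls.from_dict(data)


class SimState:
    """Mutable simulation state: grid, agents, RNG streams, metrics."""

    def __init__(self, cfg: SimConfig):
        self.tick = 0
        self.grid = CryptGrid(cfg.n_layers, cfg.n_cols)
        self.cells: dict = {}
        self.immune: list = []
        self.rng = random.Random(cfg.seed)
        self.nprng = np.random.default_rng(cfg.seed)
        self._cell_ids = itertools.count()
        self._immune_ids = itertools.count()
        self.metrics = Metrics(cfg.n_layers)

    def next_cell_id(self) -> int:
        return next(self._cell_ids)

    def next_immune_id(self) -> int:
        return next(self._immune_ids)


@dataclass
class RunResult:
    """Outcome of one run: final state, metrics and the stop reason."""

    config: SimConfig
    state: SimState
    metrics: Metrics
    stop_reason: str
    n_ticks: int


def _make_context(state: SimState, cfg: SimConfig) -> StepContext:
    def kill(cell: Cell, cause: str) -> None:
        state.grid.remove(cell, cell.pos)
        del state.cells[cell.id]
        state.metrics.on_death(cell, cause, state.tick)

    def register_birth(parent, cell: Cell, kind: str) -> None:
        state.cells[cell.id] = cell
        state.metrics.on_birth(parent, cell, kind)

    return StepContext(
        grid=state.grid,
        model=cfg.mutation_model(),
        schedule=cfg.schedule,
        rng=state.rng,
        nprng=state.nprng,
        tick=0,
        new_id=state.next_cell_id,
        kill=kill,
        register_birth=register_birth,
        gap_fill_resets_clock=cfg.gap_fill_resets_clock,
    )


def _fresh_base_cell(state: SimState, cfg: SimConfig, ctx: StepContext, col: int) -> Cell:
    """A new transit-amplifying cell for an empty base spot (stem niche)."""
    genotype = sample_initial_genotype(cfg.p_het, state.rng)
    cell = Cell(
        state.next_cell_id(),
        0,
        col,
        Typology.TRANSIT_AMPLIFYING,
        genotype,
        ctx.model,
        age=0,
        birth_tick=state.tick,
    )
    cell.lifespan = sample_lifespan(cell.typology, state.rng)
    cell.mitosis_clock = _initial_clock(cell, cfg, state.rng)
    return cell


def _initial_clock(cell: Cell, cfg: SimConfig, rng) -> int:
    """Uniform residual waiting time, to avoid a synchronized division wave."""
    if cell.typology == Typology.TUMORAL:
        mean = cfg.schedule.mean_tumoral
    elif cell.kras_mut:
        mean = cfg.schedule.mean_kras_het
    else:
        mean = cfg.schedule.mean_physiological
    return rng.randint(1, max(1, round(mean)))


def initialize(cfg: SimConfig) -> SimState:
    """Build the initial crypt: one cell per spot, 25/75 TA/differentiated.

    The typology boundary follows the beta-catenin threshold (the bottom
    quarter of layers stays transit-amplifying on the default grid).  Ages
    are uniform on [0, lifespan) and clocks uniform on [1, mean] so the
    population starts near its renewal equilibrium rather than as a
    synchronized cohort.
    """
    state = SimState(cfg)
    ctx = _make_context(state, cfg)
    for layer in range(cfg.n_layers):
        ta = state.grid.beta_catenin(layer) >= cfg.theta_diff
        typology = Typology.TRANSIT_AMPLIFYING if ta else Typology.DIFFERENTIATED
        for col in range(cfg.n_cols):
            genotype = sample_initial_genotype(cfg.p_het, state.rng)
            cell = Cell(
                state.next_cell_id(),
                layer,
                col,
                typology,
                genotype,
                ctx.model,
                birth_tick=0,
            )
            cell.lifespan = sample_lifespan(typology, state.rng)
            cell.age = state.rng.randint(0, cell.lifespan - 1)
            cell.birth_tick = -cell.age
            cell.mitosis_clock = _initial_clock(cell, cfg, state.rng)
            state.grid.place(cell, cell.pos)
            ctx.register_birth(None, cell, "initial")
    state.metrics.record_tick(state)
    return state


def step(state: SimState, cfg: SimConfig, ctx: Optional[StepContext] = None) -> None:
    """Advance the simulation by one tick (see module docstring for phases)."""
    if ctx is None:
        ctx = _make_context(state, cfg)
    state.tick += 1
    ctx.tick = state.tick
    grid = state.grid
    metrics = state.metrics
    rng = state.rng

    # (1) epithelial cells act in a freshly shuffled order
    order = list(state.cells.values())
    rng.shuffle(order)
    cells = state.cells
    blocked = []
    for cell in order:
        if cell.id not in cells:
            continue  # eliminated earlier this tick
        cause = age_and_check_death(cell, ctx.model)
        if cause is not None:
            ctx.kill(cell, cause)
            continue
        if cell.typology == Typology.TRANSIT_AMPLIFYING:
            new_t = differentiate(cell, grid.beta, cfg.theta_diff)
            if new_t is not cell.typology:
                metrics.on_typology_change(cell, cell.typology, new_t)
                cell.typology = new_t
        outcome = move(cell, grid, rng, cfg.p_slow)
        if outcome == "exited":
            grid.remove(cell, cell.pos)
            del cells[cell.id]
            metrics.on_exit(cell, state.tick)
            continue
        if outcome == "blocked":
            blocked.append(cell)
        cell.mitosis_clock -= 1
        if cell.mitosis_clock <= 0:
            attempt_scheduled_mitosis(cell, ctx)

    # (1b) deferred advances: vacancies opened later in the pass (exits,
    # deaths, moves) let blocked cells complete their one-layer migration,
    # so the column flows one layer per hour as a whole
    progress = True
    while progress and blocked:
        progress = False
        remaining = []
        for cell in blocked:
            if cell.id not in cells:
                continue
            if try_advance(cell, grid):
                progress = True
            else:
                remaining.append(cell)
        blocked = remaining

    # (2) gap filling
    gap_fill(ctx)

    # (3) hypoxic overcrowding
    for victim in hypoxia_cull(grid, cfg.env, rng):
        ctx.kill(victim, "hypoxic")

    # (4) immune system
    for agent in spawn_immune(grid, cfg.env, rng, state.next_immune_id):
        state.immune.append(agent)
        metrics.immune_spawned += 1
    agents = list(state.immune)
    rng.shuffle(agents)
    for agent in agents:
        action, victim = immune_step(agent, grid, cfg.env, rng)
        if action == "killed":
            ctx.kill(victim, "immune")
            metrics.immune_kills += 1
            if agent.kills_remaining <= 0:
                state.immune.remove(agent)
                metrics.immune_expired += 1

    # (5) stem-niche replenishment: every base spot vacated this hour is
    # refilled with a fresh transit-amplifying cell before the hour closes
    # (cyclically identical to refilling at the start of the next tick, but
    # observers then always see a full epithelium)
    for col in range(cfg.n_cols):
        if grid.spot_count((0, col)) == 0:
            cell = _fresh_base_cell(state, cfg, ctx, col)
            grid.place(cell, cell.pos)
            ctx.register_birth(None, cell, "replenish")

    # (6) observers
    metrics.record_tick(state)


def check_stop(state: SimState, cfg: SimConfig) -> Optional[str]:
    """Return the stop reason fired by the current state, if any."""
    if state.tick >= cfg.stop.max_ticks:
        return "year_elapsed"
    if cfg.stop.proportion_inversion:
        counts = state.metrics.typology_counts
        if counts[Typology.TRANSIT_AMPLIFYING] > counts[Typology.DIFFERENTIATED]:
            return "proportion_inverted"
    if state.metrics.live >= cfg.stop.pop_cap:
        return "pop_cap"
    return None


def run(cfg: SimConfig) -> RunResult:
    """Run a scenario until a stop condition fires."""
    state = initialize(cfg)
    ctx = _make_context(state, cfg)
    reason = check_stop(state, cfg)
    while reason is None:
        step(state, cfg, ctx)
        reason = check_stop(state, cfg)
    state.metrics.finalize(state)
    return RunResult(
        config=cfg,
        state=state,
        metrics=state.metrics,
        stop_reason=reason,
        n_ticks=state.tick,
    )


def run_sweep(
    probs=SCENARIO_PROBS,
    replicates: int = 1,
    base_cfg: Optional[SimConfig] = None,
    seed0: int = 0,
) -> list:
    """Run the mutation-probability scenario grid with replicate seeds.

    Returns a flat list of :class:`RunResult`, ordered by scenario then
    replicate; replicate ``r`` of any scenario uses seed ``seed0 + r`` so
    scenarios are paired across the sweep.
    """
    if base_cfg is None:
        base_cfg = SimConfig()
    results = []
    for prob in probs:
        for r in range(replicates):
            cfg = base_cfg.replace(base_prob=prob, seed=seed0 + r)
            results.append(run(cfg))
    return results
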