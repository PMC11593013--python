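"""Per-cell behaviour: aging, death, differentiation, movement, mitosis.

Each tick (1 h) a cell ages, may die (lifespan, gatekeeper apoptosis), may
differentiate (transit-amplifying cells below the beta-catenin threshold),
moves according to its typology, and divides when its mitosis clock expires.

Movement by typology
    * physiological (transit-amplifying / differentiated): one layer up, only
      if the spot ahead is empty; from the top layer the move is an exit.
    * pre-adenoma / adenoma: diagonal drift (layer+1, col+-1) regardless of
      occupancy (stacking allowed); with probability ``p_slow`` the cell skips
      the advance that tick (the slower migration of APC-null cells).
    * tumoral: immobile.

Mitosis
    The daughter spot is drawn from the typology's allowed proliferation
    directions (physiological: lateral; pre-adenoma/adenoma: lateral and
    upper diagonals; tumoral: all eight).  Physiological dividers blocked on
    all sides eliminate the least-fit neighbour (fewest mitoses, then oldest,
    then random) to make room; neoplastic dividers stack into occupied spots.
    Daughters receive an independently mutated copy of the parent genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .crypt_world import BetaCateninField, CryptGrid
from .genome import (
    Genotype,
    MutationModel,
    Typology,
    classify_typology,
    gatekeeper_apoptosis,
    mutate_genome,
    regulation_burden,
)

__all__ = [
    "Cell",
    "MitosisSchedule",
    "StepContext",
    "PROLIFERATION_DIRECTIONS",
    "LIFESPAN_RANGE",
    "LIFESPAN_RANGE_TUMORAL",
    "sample_lifespan",
    "sample_mitosis_clock",
    "differentiate",
    "move",
    "attempt_scheduled_mitosis",
    "gap_fill",
    "age_and_check_death",
    "spawn_daughter",
]

# lifespans in hours, inclusive bounds
LIFESPAN_RANGE = (96, 120)
LIFESPAN_RANGE_TUMORAL = (96, 150)

_PHYS_DIRS = ("left", "right")
_NEO_DIRS = ("left", "right", "up_left", "up_right")
_TUMORAL_DIRS = (
    "left",
    "right",
    "up",
    "down",
    "up_left",
    "up_right",
    "down_left",
    "down_right",
)

PROLIFERATION_DIRECTIONS = {
    Typology.TRANSIT_AMPLIFYING: _PHYS_DIRS,
    Typology.DIFFERENTIATED: _PHYS_DIRS,
    Typology.PRE_ADENOMA: _NEO_DIRS,
    Typology.ADENOMA: _NEO_DIRS,
    Typology.TUMORAL: _TUMORAL_DIRS,
}


@dataclass(frozen=True)
class MitosisSchedule:
    """Mitosis waiting-time model: Normal(mean, variance), >= 1 h, whole ticks.

    The mean is 24 h for physiological cells, 12 h once KRAS activation is
    phenotypically expressed (the adenoma typology: APC lost plus at least
    one mutated KRAS allele) and 10 h for tumoral cells.  Keying the 12 h
    cycle to the adenoma phenotype rather than to bare KRAS heterozygosity
    keeps the physiological crypt selectively neutral, which is what holds
    the driver-genotype frequencies at their stem-niche values (0.50
    wild-type / 0.25 per heterozygote class) in low-mutation runs.
    """

    mean_physiological: float = 24.0
    mean_kras_het: float = 12.0
    mean_tumoral: float = 10.0
    variance: float = 1.0

    @property
    def sd(self) -> float:
        return self.variance**0.5


class Cell:
    """One epithelial cell agent.

    The genotype is fixed at birth (mutation happens only at division), so
    the typology triggers, regulation burden and gatekeeper verdict are
    cached at construction.
    """

    __slots__ = (
        "id",
        "layer",
        "col",
        "typology",
        "age",
        "lifespan",
        "mitosis_clock",
        "mitosis_count",
        "genotype",
        "tp53_null_mitoses",
        "birth_tick",
        "reg_burden",
        "gatekeeper_doomed",
        "apc_null",
        "kras_mut",
        "tp53_null",
        "gene_classes",
    )

    def __init__(
        self,
        cell_id: int,
        layer: int,
        col: int,
        typology: Typology,
        genotype: Genotype,
        model: MutationModel,
        *,
        age: int = 0,
        lifespan: int = 0,
        mitosis_clock: int = 1,
        birth_tick: int = 0,
    ):
        self.id = cell_id
        self.layer = layer
        self.col = col
        self.typology = typology
        self.age = age
        self.lifespan = lifespan
        self.mitosis_clock = mitosis_clock
        self.mitosis_count = 0
        self.genotype = genotype
        self.tp53_null_mitoses = 0
        self.birth_tick = birth_tick
        self.reg_burden = regulation_burden(genotype)
        self.gatekeeper_doomed = gatekeeper_apoptosis(genotype, model)
        self.apc_null = genotype.apc_inactivated
        self.kras_mut = genotype.kras_activated
        self.tp53_null = genotype.tp53_inactivated
        self.gene_classes = (
            genotype.driver_class(0),
            genotype.driver_class(1),
            genotype.driver_class(2),
        )

    @property
    def pos(self) -> tuple:
        return (self.layer, self.col)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Cell(id={self.id}, pos=({self.layer},{self.col}), "
            f"{self.typology.name}, age={self.age}/{self.lifespan})"
        )


@dataclass
class StepContext:
    """Wiring a cell-level operation needs from the engine.

    ``rng`` is a ``random.Random`` for scalar decisions, ``nprng`` a numpy
    Generator for the mutation draws.  ``kill`` removes a cell from the
    simulation recording the given death cause; ``register_birth`` enters a
    new cell into the simulation state (kind is one of ``scheduled``,
    ``gap_fill``, ``replenish``, ``initial``).
    """

    grid: CryptGrid
    model: MutationModel
    schedule: MitosisSchedule
    rng: object
    nprng: object
    tick: int = 0
    new_id: Callable[[], int] = None
    kill: Callable[[Cell, str], None] = None
    register_birth: Callable[[Optional[Cell], Cell, str], None] = None
    gap_fill_resets_clock: bool = True


def sample_lifespan(typology: Typology, rng) -> int:
    """Uniform integer lifespan in hours: 96-120 physiological, 96-150 tumoral."""
    lo, hi = LIFESPAN_RANGE_TUMORAL if typology == Typology.TUMORAL else LIFESPAN_RANGE
    return rng.randint(lo, hi)


def sample_mitosis_clock(cell: Cell, schedule: MitosisSchedule, rng) -> int:
    """Draw the hours until the next scheduled division for ``cell``."""
    if cell.typology == Typology.TUMORAL:
        mean = schedule.mean_tumoral
    elif cell.kras_mut:
        mean = schedule.mean_kras_het
    else:
        mean = schedule.mean_physiological
    return max(1, round(rng.gauss(mean, schedule.sd)))


def differentiate(cell: Cell, field: BetaCateninField, theta: float) -> Typology:
    """Transit-amplifying -> differentiated below the beta-catenin threshold.

    APC-null cells never differentiate (but those are classified neoplastic at
    birth); APC heterozygotes retain normal differentiation control.
    """
    if (
        cell.typology == Typology.TRANSIT_AMPLIFYING
        and not cell.apc_null
        and field.value_at_layer(cell.layer) < theta
    ):
        return Typology.DIFFERENTIATED
    return cell.typology


def _relocate(cell: Cell, grid: CryptGrid, new_pos) -> None:
    grid.remove(cell, cell.pos)
    grid.place(cell, new_pos)
    cell.layer, cell.col = new_pos


def move(cell: Cell, grid: CryptGrid, rng, p_slow: float = 0.25) -> str:
    """Advance the cell one layer according to its typology.

    Returns ``"moved"``, ``"stayed"``, ``"blocked"`` (a physiological cell
    whose spot ahead is occupied; it may still complete the advance this tick
    via :func:`try_advance` once the blocker has moved on) or ``"exited"``
    (a move upward from the top layer; the caller removes the cell and counts
    an exit, not a death).
    """
    t = cell.typology
    if t == Typology.TUMORAL:
        return "stayed"
    if t.physiological:
        if cell.layer == grid.top_layer:
            return "exited"
        ahead = (cell.layer + 1, cell.col)
        if grid.spot_count(ahead) == 0:
            _relocate(cell, grid, ahead)
            return "moved"
        return "blocked"
    # pre-adenoma / adenoma: diagonal drift, stacking allowed
    if rng.random() < p_slow:
        return "stayed"
    if cell.layer == grid.top_layer:
        return "exited"
    dc = -1 if rng.random() < 0.5 else 1
    target = (cell.layer + 1, grid.wrap_col(cell.col + dc))
    _relocate(cell, grid, target)
    return "moved"


def try_advance(cell: Cell, grid: CryptGrid) -> bool:
    """Complete a deferred one-layer advance if the spot ahead has emptied.

    The epithelium migrates as a column: one spot freed at the crypt mouth
    lets every cell below shift up one layer within the same hour.  A cell
    that found its path blocked during its own turn therefore re-checks the
    spot ahead after the rest of the column has acted; each cell still
    advances at most one layer per tick.
    """
    ahead = (cell.layer + 1, cell.col)
    if grid.spot_count(ahead) == 0:
        _relocate(cell, grid, ahead)
        return True
    return False


def spawn_daughter(parent: Cell, target_pos, ctx: StepContext, kind: str) -> Cell:
    """Create, place and register the daughter of a dividing cell.

    The daughter genome is an independently mutated copy of the parent's
    (mutation probability raised by the parent's post-TP53-loss division
    count); its typology is re-classified from the mutated genome.  The
    parent's mitosis bookkeeping is updated here.
    """
    g = mutate_genome(parent.genotype, ctx.model, parent.tp53_null_mitoses, ctx.nprng)
    typology = classify_typology(g, parent.typology)
    daughter = Cell(
        ctx.new_id(),
        target_pos[0],
        target_pos[1],
        typology,
        g,
        ctx.model,
        age=0,
        birth_tick=ctx.tick,
    )
    daughter.lifespan = sample_lifespan(typology, ctx.rng)
    daughter.mitosis_clock = sample_mitosis_clock(daughter, ctx.schedule, ctx.rng)
    parent.mitosis_count += 1
    if parent.tp53_null:
        parent.tp53_null_mitoses += 1
    ctx.grid.place(daughter, target_pos)
    ctx.register_birth(parent, daughter, kind)
    return daughter


def attempt_scheduled_mitosis(cell: Cell, ctx: StepContext) -> str:
    """Divide a cell whose mitosis clock has expired.

    Returns ``"divided"``, ``"divided_by_kill"`` (a physiological divider
    eliminated a neighbour to make room) or ``"deferred"`` (no allowed target
    position exists; the clock stays expired and the cell retries next tick).
    """
    grid = ctx.grid
    rng = ctx.rng
    positions = grid.neighbors(cell.pos, PROLIFERATION_DIRECTIONS[cell.typology])
    if not positions:
        return "deferred"
    empty = [p for p in positions if grid.spot_count(p) == 0]
    outcome = "divided"
    if empty:
        target = empty[rng.randrange(len(empty))]
    elif cell.typology.physiological:
        # blocked: eliminate the least-fit adjacent occupant (fewest
        # divisions, then oldest, then uniformly at random)
        candidates = [c for p in positions for c in grid.cells_at(p)]
        best_key = min((c.mitosis_count, -c.age) for c in candidates)
        ties = [c for c in candidates if (c.mitosis_count, -c.age) == best_key]
        victim = ties[rng.randrange(len(ties))]
        target = victim.pos
        ctx.kill(victim, "physiological")
        outcome = "divided_by_kill"
    else:
        # neoplastic dividers stack into occupied spots
        target = positions[rng.randrange(len(positions))]
    spawn_daughter(cell, target, ctx, "scheduled")
    cell.mitosis_clock = sample_mitosis_clock(cell, ctx.schedule, rng)
    return outcome


def gap_fill(ctx: StepContext) -> int:
    """Fill empty spots by forced lateral divisions; returns fills performed.

    Each empty spot with at least one lateral physiological occupant is filled
    by a division of one of them (side chosen equiprobably among occupied
    sides, then a uniform physiological occupant of that side).  Iterates to a
    fixed point so that a run of same-tick deaths still heals, but each gap is
    filled by exactly one division.
    """
    grid = ctx.grid
    rng = ctx.rng
    pending = grid.empty_spots()
    fills = 0
    progress = True
    while pending and progress:
        progress = False
        still_empty = []
        for pos in pending:
            layer, col = pos
            sides = []
            for dc in (-1, 1):
                occupants = [
                    c
                    for c in grid.cells_at((layer, grid.wrap_col(col + dc)))
                    if c.typology.physiological
                ]
                if occupants:
                    sides.append(occupants)
            if not sides:
                still_empty.append(pos)
                continue
            occupants = sides[rng.randrange(len(sides))]
            parent = occupants[rng.randrange(len(occupants))]
            spawn_daughter(parent, pos, ctx, "gap_fill")
            if ctx.gap_fill_resets_clock:
                parent.mitosis_clock = sample_mitosis_clock(parent, ctx.schedule, rng)
            fills += 1
            progress = True
        pending = still_empty
    return fills


def age_and_check_death(cell: Cell, model: MutationModel) -> Optional[str]:
    """Age the cell by one tick; return its death cause, or None if alive.

    Causes: ``"physiological"`` (lifespan reached by a non-tumoral cell, or
    gatekeeper apoptosis), ``"tumoral"`` (a tumoral cell past its lifespan).
    """
    cell.age += 1
    if cell.gatekeeper_doomed:
        return "physiological"
    if cell.age > cell.lifespan:
        return "tumoral" if cell.typology == Typology.TUMORAL else "physiological"
    return None
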