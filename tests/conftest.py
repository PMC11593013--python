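"""Shared fixtures: a small-world harness for cell-level operations."""

import itertools
import random

import numpy as np
import pytest

from cryptsim.cell_dynamics import Cell, MitosisSchedule, StepContext, sample_lifespan
from cryptsim.crypt_world import CryptGrid
from cryptsim.genome import Genotype, MutationModel, Typology


class Harness:
    """A hand-buildable miniature crypt wired like the engine wires a run."""

    def __init__(self, n_layers=6, n_cols=5, base_prob=0.0, seed=0, **model_kw):
        self.grid = CryptGrid(n_layers, n_cols)
        self.model = MutationModel(base_prob=base_prob, **model_kw)
        self.schedule = MitosisSchedule()
        self.rng = random.Random(seed)
        self.nprng = np.random.default_rng(seed)
        self.cells = {}
        self.killed = []
        self.births = []
        self._ids = itertools.count(0)
        self.ctx = StepContext(
            grid=self.grid,
            model=self.model,
            schedule=self.schedule,
            rng=self.rng,
            nprng=self.nprng,
            tick=0,
            new_id=lambda: next(self._ids),
            kill=self._kill,
            register_birth=self._birth,
        )

    def _kill(self, cell, cause):
        self.grid.remove(cell, cell.pos)
        del self.cells[cell.id]
        self.killed.append((cell, cause))

    def _birth(self, parent, cell, kind):
        self.cells[cell.id] = cell
        self.births.append((parent, cell, kind))

    def add(
        self,
        layer,
        col,
        typology=Typology.TRANSIT_AMPLIFYING,
        genotype=None,
        age=0,
        lifespan=None,
        mitosis_clock=10,
        mitosis_count=0,
    ):
        cell = Cell(
            next(self._ids),
            layer,
            col,
            typology,
            genotype or Genotype.wildtype(),
            self.model,
            age=age,
            mitosis_clock=mitosis_clock,
        )
        cell.lifespan = (
            lifespan if lifespan is not None else sample_lifespan(typology, self.rng)
        )
        cell.mitosis_count = mitosis_count
        self.grid.place(cell, cell.pos)
        self.cells[cell.id] = cell
        return cell


@pytest.fixture
def harness():
    return Harness()


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def nprng():
    return np.random.default_rng(12345)
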