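"""Measurement surfaces: time series, death ledger, histograms, exports.

The :class:`Metrics` accumulator is driven by engine callbacks (birth, death,
exit, typology change, division) plus one ``record_tick`` per tick.  It keeps

* population counts per typology and immune-agent counts per tick,
* a death ledger by cause (physiological, hypoxic, immune, tumoral) and exits,
* driver-genotype class counts (APC/KRAS/TP53 x {00,01,10,11}) among live
  epithelial cells,
* a division-event histogram by crypt layer,
* per-typology histograms of per-cell division counts (over all cells ever),
* the per-spot occupancy distribution at the tick of maximum neoplastic
  population,
* residence-time extremes (ticks from creation to exit or death).

All tables are tidy (one observation per row) and exports are deterministic.
"""

from __future__ import annotations

import json
import os
from collections import Counter

import numpy as np
import pandas as pd

from .genome import Typology

__all__ = [
    "DEATH_CAUSES",
    "GENE_NAMES",
    "GENE_CLASSES",
    "Metrics",
    "death_rate_series",
    "occupancy_histogram_at_peak",
    "snapshot_frame",
    "export",
]

DEATH_CAUSES = ("physiological", "hypoxic", "immune", "tumoral")
GENE_NAMES = ("APC", "KRAS", "TP53")
GENE_CLASSES = ("00", "01", "10", "11")
_TYPOLOGY_COLS = [t.name.lower() for t in Typology]


class Metrics:
    """Per-run observation accumulator (see module docstring)."""

    def __init__(self, n_layers: int = 100):
        self.n_layers = n_layers
        # live-state counters, maintained incrementally
        self.live = 0
        self.typology_counts = np.zeros(len(Typology), dtype=np.int64)
        self.gene_class_counts = np.zeros((3, 4), dtype=np.int64)
        # cumulative ledgers
        self.created_total = 0
        self.created_by_kind = Counter()
        self.deaths_total = Counter()
        self.exits_total = 0
        self.divisions_total = 0
        self.immune_spawned = 0
        self.immune_expired = 0
        self.immune_kills = 0
        # per-tick accumulators (flushed by record_tick)
        self._tick_deaths = Counter()
        self._tick_exits = 0
        # histograms
        self.division_height = np.zeros(n_layers, dtype=np.int64)
        self.mitosis_hist = {t: Counter() for t in Typology}
        self.max_residence = 0
        self.residence_count = 0
        # neoplastic-peak occupancy snapshot
        self.peak_neoplastic = -1
        self.peak_tick = 0
        self.peak_occupancy = None
        # time series rows
        self._rows = []

    # -- engine callbacks ----------------------------------------------------
    def on_birth(self, parent, cell, kind: str) -> None:
        self.live += 1
        self.created_total += 1
        self.created_by_kind[kind] += 1
        self.typology_counts[cell.typology] += 1
        for gene in range(3):
            self.gene_class_counts[gene, cell.gene_classes[gene]] += 1
        if parent is not None:
            self.divisions_total += 1
            self.division_height[parent.layer] += 1

    def _on_remove(self, cell, tick: int) -> None:
        self.live -= 1
        self.typology_counts[cell.typology] -= 1
        for gene in range(3):
            self.gene_class_counts[gene, cell.gene_classes[gene]] -= 1
        self.mitosis_hist[cell.typology][cell.mitosis_count] += 1
        residence = tick - cell.birth_tick
        self.residence_count += 1
        if residence > self.max_residence:
            self.max_residence = residence

    def on_death(self, cell, cause: str, tick: int) -> None:
        self.deaths_total[cause] += 1
        self._tick_deaths[cause] += 1
        self._on_remove(cell, tick)

    def on_exit(self, cell, tick: int) -> None:
        self.exits_total += 1
        self._tick_exits += 1
        self._on_remove(cell, tick)

    def on_typology_change(self, cell, old: Typology, new: Typology) -> None:
        self.typology_counts[old] -= 1
        self.typology_counts[new] += 1

    # -- per-tick recording --------------------------------------------------
    def record_tick(self, state) -> None:
        neo = int(
            self.typology_counts[Typology.PRE_ADENOMA]
            + self.typology_counts[Typology.ADENOMA]
            + self.typology_counts[Typology.TUMORAL]
        )
        if neo > self.peak_neoplastic:
            self.peak_neoplastic = neo
            self.peak_tick = state.tick
            counts = state.grid.occupancy_counts().ravel()
            self.peak_occupancy = np.bincount(counts)
        row = (
            state.tick,
            *self.typology_counts,
            len(state.immune),
            self.live,
            *(self._tick_deaths.get(c, 0) for c in DEATH_CAUSES),
            self._tick_exits,
            self.created_total,
            *self.gene_class_counts.ravel(),
        )
        self._rows.append(row)
        self._tick_deaths = Counter()
        self._tick_exits = 0

    def finalize(self, state) -> None:
        """Fold still-live cells into the per-cell mitosis histograms."""
        for cell in state.cells.values():
            self.mitosis_hist[cell.typology][cell.mitosis_count] += 1

    # -- tabular views -------------------------------------------------------
    def _frame(self) -> pd.DataFrame:
        cols = (
            ["tick"]
            + _TYPOLOGY_COLS
            + ["immune", "live"]
            + [f"deaths_{c}" for c in DEATH_CAUSES]
            + ["exits", "created_total"]
            + [
                f"{gene}_{cls}"
                for gene in GENE_NAMES
                for cls in GENE_CLASSES
            ]
        )
        return pd.DataFrame(self._rows, columns=cols)

    def populations(self) -> pd.DataFrame:
        """Tidy per-tick population counts (typologies + immune agents)."""
        frame = self._frame()
        return frame.melt(
            id_vars="tick",
            value_vars=_TYPOLOGY_COLS + ["immune"],
            var_name="population",
            value_name="count",
        )

    def deaths(self) -> pd.DataFrame:
        """Wide per-tick death counts by cause, plus exits."""
        frame = self._frame()
        return frame[["tick"] + [f"deaths_{c}" for c in DEATH_CAUSES] + ["exits"]]

    def genotype_frequencies(self) -> pd.DataFrame:
        """Tidy per-tick driver-genotype class frequencies among live cells."""
        frame = self._frame()
        rows = []
        live = frame["live"].to_numpy(dtype=float)
        live[live == 0] = np.nan
        for gene in GENE_NAMES:
            for cls in GENE_CLASSES:
                freq = frame[f"{gene}_{cls}"].to_numpy() / live
                rows.append(
                    pd.DataFrame(
                        {
                            "tick": frame["tick"],
                            "gene": gene,
                            "genotype": cls,
                            "frequency": freq,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def wide(self) -> pd.DataFrame:
        """The raw per-tick table (one row per tick, all counters)."""
        return self._frame()

    def mitosis_histogram_frame(self) -> pd.DataFrame:
        rows = [
            (t.name.lower(), k, n)
            for t in Typology
            for k, n in sorted(self.mitosis_hist[t].items())
        ]
        return pd.DataFrame(rows, columns=["typology", "mitosis_count", "cells"])

    def height_profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer": np.arange(self.n_layers),
                "divisions": self.division_height,
            }
        )

    def occupancy_peak_frame(self) -> pd.DataFrame:
        occ = self.peak_occupancy
        if occ is None:
            occ = np.array([], dtype=np.int64)
        return pd.DataFrame(
            {
                "cells_per_spot": np.arange(len(occ)),
                "spots": occ,
            }
        )


def death_rate_series(deaths: pd.DataFrame, window: int = 24, cause=None) -> pd.Series:
    """Centered moving-average death rate (cells/hour).

    ``deaths`` is the frame from :meth:`Metrics.deaths`.  ``cause`` selects a
    single cause column; None sums all causes.  A window longer than the
    series degrades gracefully to the plain mean of the available ticks.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if cause is None:
        series = deaths[[f"deaths_{c}" for c in DEATH_CAUSES]].sum(axis=1)
    else:
        series = deaths[f"deaths_{cause}"]
    return series.rolling(window, center=True, min_periods=1).mean()


def occupancy_histogram_at_peak(result):
    """(histogram, log-linear slope) of cells-per-spot at maximum neoplastic load.

    The histogram maps occupancy class -> number of spots, taken at the tick
    where the total neoplastic population peaked.  The slope is the linear
    fit of log(spot count) against occupancy over occupied classes; for a
    physiological run (all occupancies <= 1) there is nothing to fit and the
    slope is NaN.
    """
    hist = result.metrics.peak_occupancy
    if hist is None:
        hist = np.array([], dtype=np.int64)
    occ = np.arange(len(hist))
    mask = (occ >= 1) & (hist > 0)
    if mask.sum() < 2:
        return hist, float("nan")
    slope = np.polyfit(occ[mask], np.log(hist[mask]), 1)[0]
    return hist, float(slope)


def snapshot_frame(state) -> pd.DataFrame:
    """Tidy grid snapshot: one row per live cell."""
    rows = [
        (
            state.tick,
            cell.layer,
            cell.col,
            cell.id,
            cell.typology.name.lower(),
            cell.age,
            cell.mitosis_count,
        )
        for cell in state.cells.values()
    ]
    rows.sort(key=lambda r: r[3])
    return pd.DataFrame(
        rows, columns=["tick", "layer", "col", "cell_id", "typology", "age", "mitoses"]
    )


def export(result, out_dir: str) -> dict:
    """Write all observer tables of a run as CSV plus run metadata JSON.

    Returns a mapping of logical name -> file path.  Re-exporting the same
    run produces byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    m = result.metrics
    files = {}

    def _write(name, frame):
        path = os.path.join(out_dir, name)
        try:
            frame.to_csv(path, index=False)
        except OSError as exc:  # pragma: no cover
            raise OSError(f"failed writing {path}: {exc}") from exc
        files[name] = path

    _write("populations.csv", m.populations())
    _write("deaths.csv", m.deaths())
    _write("genotype_freqs.csv", m.genotype_frequencies())
    _write("mitosis_hist.csv", m.mitosis_histogram_frame())
    _write("height_profile.csv", m.height_profile_frame())
    _write("occupancy_peak.csv", m.occupancy_peak_frame())
    snap_name = f"snapshot_{result.state.tick}.csv"
    _write(snap_name, snapshot_frame(result.state))

    from . import __version__

    meta = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "stop_reason": result.stop_reason,
        "n_ticks": result.n_ticks,
        "version": __version__,
    }
    meta_path = os.path.join(out_dir, "run_meta.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["run_meta.json"] = meta_path
    return files
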