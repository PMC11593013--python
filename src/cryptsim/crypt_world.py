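"""Crypt geometry: the spot lattice and the beta-catenin gradient.

The crypt is an unfolded cylinder: ``n_layers`` (default 100) rows of
``n_cols`` (default 25) *spots*, each spot being the 3x2-patch footprint of
one epithelial cell on the underlying 300x50-patch surface.  Layer 0 is the
crypt base, layer ``n_layers - 1`` the crypt mouth; columns wrap laterally
(periodic boundary), layers do not.  All occupancy, hypoxia and immune
thresholds in the model operate on spots, the model's own unit of placement.

Beta-catenin — the Wnt-pathway signal that keeps cells in the
transit-amplifying state — decreases linearly from 1 at the base to 0 at the
mouth; the differentiation threshold (0.75 by default) places the boundary at
the bottom quarter of the crypt, realising the 25/75 transit-amplifying /
differentiated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DIRECTIONS", "BetaCateninField", "CryptGrid"]

# (d_layer, d_col); layer increases toward the crypt mouth
DIRECTIONS = {
    "left": (0, -1),
    "right": (0, 1),
    "up": (1, 0),
    "down": (-1, 0),
    "up_left": (1, -1),
    "up_right": (1, 1),
    "down_left": (-1, -1),
    "down_right": (-1, 1),
}


@dataclass(frozen=True)
class BetaCateninField:
    """Linear base-to-mouth beta-catenin profile: 1 at layer 0, 0 at the top."""

    n_layers: int = 100

    def value_at_layer(self, layer: int) -> float:
        if not 0 <= layer < self.n_layers:
            raise IndexError(f"layer {layer} outside [0, {self.n_layers})")
        return 1.0 - layer / (self.n_layers - 1)

    __call__ = value_at_layer


class CryptGrid:
    """Spot lattice with per-spot occupancy lists and lateral wrap.

    Occupancy lists hold whatever items the caller places (the engine stores
    :class:`~cryptsim.cell_dynamics.Cell` objects; identity is the id).  Every
    live epithelial cell must appear in exactly one spot's list; ``place`` /
    ``remove`` keep that bijection and ``remove`` of an absent item raises,
    as a bookkeeping bug guard.
    """

    def __init__(self, n_layers: int = 100, n_cols: int = 25, spot_h: int = 3, spot_w: int = 2):
        if n_layers < 2 or n_cols < 1:
            raise ValueError("grid needs at least 2 layers and 1 column")
        self.n_layers = n_layers
        self.n_cols = n_cols
        self.spot_h = spot_h
        self.spot_w = spot_w
        self.beta = BetaCateninField(n_layers)
        self._occ = [[[] for _ in range(n_cols)] for _ in range(n_layers)]

    # -- geometry ------------------------------------------------------------
    def beta_catenin(self, layer: int) -> float:
        return self.beta.value_at_layer(layer)

    @property
    def n_spots(self) -> int:
        return self.n_layers * self.n_cols

    @property
    def top_layer(self) -> int:
        return self.n_layers - 1

    def wrap_col(self, col: int) -> int:
        return col % self.n_cols

    def neighbors(self, pos, directions) -> list:
        """Neighboring positions; columns wrap, out-of-range layers are omitted."""
        layer, col = pos
        out = []
        for name in directions:
            dl, dc = DIRECTIONS[name]
            nl = layer + dl
            if 0 <= nl < self.n_layers:
                out.append((nl, (col + dc) % self.n_cols))
        return out

    def col_distance(self, c1: int, c2: int) -> int:
        """Lateral distance with wrap."""
        d = abs(c1 - c2) % self.n_cols
        return min(d, self.n_cols - d)

    # -- occupancy -----------------------------------------------------------
    def cells_at(self, pos) -> list:
        """The occupancy list at ``pos`` (the live list — do not mutate)."""
        return self._occ[pos[0]][pos[1]]

    def spot_count(self, pos) -> int:
        return len(self._occ[pos[0]][pos[1]])

    def place(self, item, pos) -> None:
        self._occ[pos[0]][pos[1]].append(item)

    def remove(self, item, pos) -> None:
        try:
            self._occ[pos[0]][pos[1]].remove(item)
        except ValueError:
            raise LookupError(f"item {item!r} not present at spot {pos}") from None

    def total_count(self) -> int:
        return sum(len(spot) for row in self._occ for spot in row)

    def max_spot_count(self) -> int:
        return max(len(spot) for row in self._occ for spot in row)

    def occupancy_counts(self) -> np.ndarray:
        """(n_layers, n_cols) integer array of spot occupancies."""
        return np.array(
            [[len(spot) for spot in row] for row in self._occ], dtype=np.int64
        )

    def empty_spots(self) -> list:
        return [
            (layer, col)
            for layer, row in enumerate(self._occ)
            for col, spot in enumerate(row)
            if not spot
        ]

    def iter_spots(self):
        for layer, row in enumerate(self._occ):
            for col, spot in enumerate(row):
                yield (layer, col), spot
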