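"""Driver-gene genetics of crypt epithelial cells.

Each cell carries three colorectal-cancer driver genes — *APC* and *TP53*
(tumour suppressors, two-hit) and *KRAS* (oncogene, one-hit) — plus 50
generic *regulation genes*, every gene being a pair of binary alleles
(0 wild-type, 1 mutated).  Mutation is irreversible: alleles only ever flip
0 -> 1, so a genotype's mutational burden is monotone over a lineage.

The model's genetic rules:

* **Loss of heterozygosity** — once one allele of a gene is mutated, the
  remaining wild-type allele mutates with a probability one order of
  magnitude higher (``loh_factor``, default 10).
* **TP53 hypermutability** — a TP53-null cell ([1,1]) raises the mutation
  probability of *all* genes: the exponent of the base probability increases
  by ``tp53_exponent_step`` (default 0.5) for every mitosis performed after
  TP53 loss, capped at probability 1.
* **Gatekeeper apoptosis** — if the summed regulation-gene burden exceeds a
  threshold while TP53 is still wild-type homozygous, the cell is killed.
  TP53-mutant cells escape this check.
* **Typology triggers** — APC=[1,1] makes a cell *pre-adenoma*; adding at
  least one mutated KRAS allele makes it *adenoma*; additionally losing both
  TP53 alleles makes it *tumoral*.  Without APC loss no neoplastic typology
  is triggered and the cell keeps its physiological state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "APC",
    "KRAS",
    "TP53",
    "N_REGULATION",
    "Typology",
    "MutationModel",
    "Genotype",
    "classify_typology",
    "effective_mutation_prob",
    "mutate_gene",
    "mutate_genome",
    "regulation_burden",
    "gatekeeper_apoptosis",
    "sample_initial_genotype",
]

# gene row indices in the allele matrix
APC = 0
KRAS = 1
TP53 = 2
N_REGULATION = 50
_N_GENES = 3 + N_REGULATION
_N_ALLELES = 2 * _N_GENES


class Typology(enum.IntEnum):
    """Cell typology, ordered by neoplastic grade."""

    TRANSIT_AMPLIFYING = 0
    DIFFERENTIATED = 1
    PRE_ADENOMA = 2
    ADENOMA = 3
    TUMORAL = 4

    @property
    def neoplastic(self) -> bool:
        return self >= Typology.PRE_ADENOMA

    @property
    def physiological(self) -> bool:
        return self <= Typology.DIFFERENTIATED


@dataclass(frozen=True)
class MutationModel:
    """Parameters of the stochastic mutation process.

    Parameters
    ----------
    base_prob
        Per-allele, per-mitosis point-mutation probability (dimensionless).
        The scenario sweep of interest spans 1e-9 .. 1e-2.
    loh_factor
        Multiplier applied to the second allele of a gene whose partner is
        already mutated (loss of heterozygosity), default 10.
    tp53_exponent_step
        Exponent increment per post-TP53-loss mitosis, default 0.5.
    reg_threshold
        Regulation-gene burden above which a TP53-wild-type cell undergoes
        gatekeeper apoptosis.
    """

    base_prob: float
    loh_factor: float = 10.0
    tp53_exponent_step: float = 0.5
    reg_threshold: int = 25

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_prob <= 1.0:
            raise ValueError(f"base_prob must be in [0, 1], got {self.base_prob}")
        if self.loh_factor < 1.0:
            raise ValueError(f"loh_factor must be >= 1, got {self.loh_factor}")
        if self.tp53_exponent_step < 0.0:
            raise ValueError(
                f"tp53_exponent_step must be >= 0, got {self.tp53_exponent_step}"
            )
        if not 0 < self.reg_threshold <= 2 * N_REGULATION:
            raise ValueError(
                f"reg_threshold must be in (0, {2 * N_REGULATION}], got {self.reg_threshold}"
            )


class Genotype:
    """Immutable-by-convention allele matrix: 53 genes x 2 alleles (uint8).

    Row 0 is APC, row 1 KRAS, row 2 TP53, rows 3..52 the regulation genes.
    Mutation operators always return a *new* Genotype; instances may therefore
    be shared between a parent and its unmutated daughters.
    """

    __slots__ = ("alleles",)

    def __init__(self, alleles=None):
        if alleles is None:
            arr = np.zeros((_N_GENES, 2), dtype=np.uint8)
        else:
            arr = np.ascontiguousarray(alleles, dtype=np.uint8)
            if arr.shape != (_N_GENES, 2):
                raise ValueError(
                    f"allele matrix must have shape ({_N_GENES}, 2), got {arr.shape}"
                )
            if arr.max(initial=0) > 1:
                raise ValueError("allele values must be 0 or 1")
        self.alleles = arr

    @classmethod
    def wildtype(cls) -> "Genotype":
        return cls()

    @classmethod
    def from_driver_pairs(cls, apc=(0, 0), kras=(0, 0), tp53=(0, 0), regulation=None) -> "Genotype":
        arr = np.zeros((_N_GENES, 2), dtype=np.uint8)
        arr[APC] = apc
        arr[KRAS] = kras
        arr[TP53] = tp53
        if regulation is not None:
            reg = np.asarray(regulation, dtype=np.uint8)
            if reg.shape != (N_REGULATION, 2):
                raise ValueError(
                    f"regulation must have shape ({N_REGULATION}, 2), got {reg.shape}"
                )
            arr[3:] = reg
        return cls(arr)

    @classmethod
    def _from_trusted(cls, arr: np.ndarray) -> "Genotype":
        g = cls.__new__(cls)
        g.alleles = arr
        return g

    # -- driver-pair views ---------------------------------------------------
    @property
    def apc(self) -> tuple:
        return (int(self.alleles[APC, 0]), int(self.alleles[APC, 1]))

    @property
    def kras(self) -> tuple:
        return (int(self.alleles[KRAS, 0]), int(self.alleles[KRAS, 1]))

    @property
    def tp53(self) -> tuple:
        return (int(self.alleles[TP53, 0]), int(self.alleles[TP53, 1]))

    @property
    def regulation(self) -> np.ndarray:
        return self.alleles[3:]

    # -- trigger predicates --------------------------------------------------
    @property
    def apc_inactivated(self) -> bool:
        return bool(self.alleles[APC, 0] and self.alleles[APC, 1])

    @property
    def kras_activated(self) -> bool:
        return bool(self.alleles[KRAS, 0] or self.alleles[KRAS, 1])

    @property
    def tp53_inactivated(self) -> bool:
        return bool(self.alleles[TP53, 0] and self.alleles[TP53, 1])

    def driver_class(self, gene: int) -> int:
        """Class index 0..3 of a driver pair: 2*a1 + a2 (00, 01, 10, 11)."""
        return int(2 * self.alleles[gene, 0] + self.alleles[gene, 1])

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and bool(
            np.array_equal(self.alleles, other.alleles)
        )

    def __hash__(self):  # pragma: no cover - identity hashing is intentional
        return id(self)

    def __repr__(self) -> str:
        return (
            f"Genotype(APC={self.apc}, KRAS={self.kras}, TP53={self.tp53}, "
            f"reg_burden={regulation_burden(self)})"
        )


def classify_typology(g: Genotype, current: Typology) -> Typology:
    """Return the highest-grade neoplastic typology triggered by ``g``.

    All neoplastic grades require full APC inactivation; absent that, the
    cell keeps ``current`` (transit-amplifying vs differentiated transitions
    are handled by the differentiation rule, not here).
    """
    if not g.apc_inactivated:
        return current
    if g.kras_activated:
        if g.tp53_inactivated:
            return Typology.TUMORAL
        return Typology.ADENOMA
    return Typology.PRE_ADENOMA


def effective_mutation_prob(
    model: MutationModel, g: Genotype, mitoses_since_tp53_loss: int
) -> float:
    """Per-allele mutation probability, boosted in TP53-null cells.

    TP53-wild or heterozygous cells mutate at ``base_prob``.  TP53-null cells
    gain ``tp53_exponent_step`` on the probability exponent per mitosis
    performed since the loss, capped at 1.
    """
    if mitoses_since_tp53_loss < 0:
        raise ValueError("mitoses_since_tp53_loss must be >= 0")
    p = model.base_prob
    if not g.tp53_inactivated or p == 0.0:
        return p
    exponent = math.log10(p) + model.tp53_exponent_step * mitoses_since_tp53_loss
    if exponent >= 0.0:
        return 1.0
    return min(1.0, 10.0**exponent)


def mutate_gene(pair, p: float, loh_factor: float, rng) -> tuple:
    """Stochastically mutate one allele pair.

    Both alleles are evaluated against the pair state *at entry*: a wild-type
    allele whose partner is already mutated flips with ``min(1, p*loh_factor)``
    (loss of heterozygosity), otherwise with ``p``.  Mutated alleles never
    revert.  ``rng`` needs only a ``random()`` method.
    """
    a1, a2 = int(pair[0]), int(pair[1])
    p = min(1.0, max(0.0, p))
    p_loh = min(1.0, p * loh_factor)
    new1, new2 = a1, a2
    if a1 == 0 and rng.random() < (p_loh if a2 else p):
        new1 = 1
    if a2 == 0 and rng.random() < (p_loh if a1 else p):
        new2 = 1
    return (new1, new2)


def mutate_genome(
    g: Genotype, model: MutationModel, mitoses_since_tp53_loss: int, rng
) -> Genotype:
    """Apply one round of replication-linked mutation to every gene.

    Equivalent to calling :func:`mutate_gene` on APC, KRAS, TP53 and all 50
    regulation pairs with ``p = effective_mutation_prob(...)``, using each
    pair's state at entry.  Returns the input object itself when no allele
    flips (genotypes are immutable, so sharing is safe).

    ``rng`` must be a :class:`numpy.random.Generator`.

    Implementation note: alleles are drawn by exact thinning — a binomial
    count of candidate sites at the per-allele upper bound ``min(1, p*loh)``,
    each candidate then accepted with ``p_site / p_max`` — which matches the
    independent per-allele Bernoulli draws in distribution while skipping
    all work for the (overwhelmingly common, at low p) mutation-free case.
    """
    p = effective_mutation_prob(model, g, mitoses_since_tp53_loss)
    if p <= 0.0:
        return g
    p_max = min(1.0, p * model.loh_factor)
    n_candidates = int(rng.binomial(_N_ALLELES, p_max))
    if n_candidates == 0:
        return g
    flat = g.alleles.reshape(-1)
    idx = rng.choice(_N_ALLELES, size=n_candidates, replace=False)
    u = rng.random(n_candidates)
    accept_plain = p / p_max
    flips = []
    for i, ui in zip(idx, u):
        if flat[i]:
            continue  # already mutated, never reverts
        partner = flat[i ^ 1]  # other allele of the same gene
        threshold = 1.0 if partner else accept_plain
        if ui < threshold:
            flips.append(i)
    if not flips:
        return g
    arr = g.alleles.copy()
    arr.reshape(-1)[flips] = 1
    return Genotype._from_trusted(arr)


def regulation_burden(g: Genotype) -> int:
    """Total number of mutated regulation alleles (0..100)."""
    return int(g.alleles[3:].sum())


def gatekeeper_apoptosis(g: Genotype, model: MutationModel) -> bool:
    """True when accumulated regulation damage triggers TP53-mediated death.

    Fires only while TP53 is wild-type homozygous; any TP53 mutation
    (heterozygous included) disables the gatekeeper.
    """
    if g.alleles[TP53, 0] or g.alleles[TP53, 1]:
        return False
    return regulation_burden(g) > model.reg_threshold


def sample_initial_genotype(p_het: float, rng) -> Genotype:
    """Draw a first-line (stem-niche) genotype.

    Independently for each driver gene, with probability ``p_het`` the pair is
    heterozygous ([1,0] or [0,1], equiprobable); otherwise wild-type.  All
    regulation genes start wild-type.  ``rng`` needs only ``random()``.
    """
    if not 0.0 <= p_het <= 1.0:
        raise ValueError(f"p_het must be in [0, 1], got {p_het}")
    arr = np.zeros((_N_GENES, 2), dtype=np.uint8)
    for gene in (APC, KRAS, TP53):
        if rng.random() < p_het:
            arr[gene, 0 if rng.random() < 0.5 else 1] = 1
    return Genotype._from_trusted(arr)
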