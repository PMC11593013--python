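# Model and methods

`cryptsim` simulates the initiation of colorectal neoplasia inside a single
colonic crypt as an agent-based model.  This note records the model, its
assumptions, the parameters that matter, the numerical choices, and what the
simulator does and does not claim about real crypts.

## World

The crypt is treated as an unfolded cylinder: a lattice of 100 layers x 25
columns of *spots*, each spot the 3x2-patch footprint of one epithelial
cell on a 300x50-patch surface.  Columns wrap laterally (periodic boundary);
layer 0 is the crypt base, layer 99 the mouth.  A cell moving upward from the
top layer exits the simulation — exits are counted separately from deaths.
One tick is one hour.

Beta-catenin, the Wnt-pathway signal that keeps enterocytes in the
transit-amplifying (TA) state, is a static linear field: 1 at the base, 0 at
the mouth.  TA cells below the differentiation threshold `theta_diff = 0.75`
differentiate, which places the TA/differentiated boundary at the bottom
quarter of layers and fixes the 25/75 TA/differentiated proportion reported
for real crypts.  Stem cells are not explicit agents: every base spot vacated
during an hour is refilled before the hour closes with a fresh TA cell drawn
from the initial-genotype distribution (the stem niche as a boundary
condition).

## Genetics

Each cell carries 53 genes as binary allele pairs: the drivers APC, KRAS,
TP53 plus 50 generic regulation genes.  Alleles flip only 0 -> 1 — no back
mutation — so genotypes are immutable once a cell is born and burden is
monotone along lineages.

* Mutation is replication-linked: each daughter's genome is an independently
  mutated copy of the parent's, rolled once per allele per division at
  probability `base_prob` (the scenario dial, 1e-9 .. 1e-2).
* Loss of heterozygosity: a wild-type allele whose partner is already
  mutated flips at `min(1, base_prob * loh_factor)` with `loh_factor = 10`.
* Tumour suppressors are two-hit (APC, TP53), the oncogene KRAS one-hit.
  Typology triggers: APC [1,1] -> pre-adenoma; plus any mutated KRAS allele
  -> adenoma; plus TP53 [1,1] -> tumoral.  Without APC loss nothing is
  triggered.  The tumoral trigger accepts any mutated KRAS configuration
  (one activated allele suffices for the oncogene, and [1,1] confers no
  extra effect).
* TP53-null hypermutability: once TP53 is [1,1], the mutation-probability
  exponent rises by `tp53_exponent_step = 0.5` per subsequent division of
  that cell, capped at probability 1.  The counter starts at 0 when TP53
  becomes null; daughters start their own counter.
* Gatekeeper apoptosis: a cell whose summed regulation burden exceeds
  `reg_threshold` *while TP53 is wild-type homozygous* dies (cause
  `physiological`).  Any TP53 mutation disables the gatekeeper.
  `reg_threshold = 25` (half the pair count) is a model choice: no published
  value exists for this abstract quantity; 25 leaves physiological runs
  untouched while letting high-mutation runs feel the brake.

The mutation operator is implemented by exact Bernoulli thinning (binomial
candidate count at the per-allele upper bound, acceptance `p_site/p_max`),
which is distributionally identical to independent per-allele draws
(unit-tested against a brute-force oracle) and lets unmutated daughters
share the parent's genotype object.

## Cell behaviour

Per tick, in a freshly shuffled order (single seeded stream), each cell:
ages (death when age exceeds its lifespan: uniform 96-120 h, tumoral
96-150 h), differentiates if eligible, moves, then divides if its mitosis
clock expired.

Movement by typology: physiological cells advance one layer iff the spot
ahead is empty; pre-adenoma/adenoma drift diagonally (layer+1, col+-1)
regardless of occupancy, skipping the advance with probability
`p_slow = 0.25` (the slowed migration of APC-null cells; the magnitude is a
model choice, no published value exists); tumoral cells never move.

Because the epithelium migrates as a column, a cell blocked during its own
turn completes its single one-layer advance once the blocker has moved on
(a deferred-advance fixed point at the end of the cell phase).  Without
this, vacancies opened by crypt-mouth exits are plugged by gap-fill
divisions near the top and the bulk never migrates; with it, an
unobstructed cell traverses the crypt in exactly 100 ticks and carries the
age~height structure a renewing epithelium must have.

Mitosis clocks are Normal(mean, 1 h^2), truncated at 1 h, rounded to whole
ticks.  Means: 24 h physiological, 12 h for KRAS-mutant cells, 10 h
tumoral.  On expiry the daughter spot is drawn from the typology's allowed
directions (physiological: lateral; pre-adenoma/adenoma: lateral + upper
diagonals; tumoral: all eight).  Empty allowed spots are preferred; a
blocked *physiological* divider eliminates the least-fit adjacent occupant
— fewest divisions, ties to the oldest, then uniform — and places the
daughter there (counted as a physiological death); blocked *neoplastic*
dividers stack into occupied spots, which is what arms the crowding
thresholds.  Gap filling runs once per tick: every empty spot with a
lateral physiological occupant is filled by one forced division (iterated
to a fixed point so runs of same-tick deaths heal, one division per gap);
the filler's clock is resampled (configurable).

## Microenvironment

A single killer-agent archetype stands in for NK cells and macrophages.
While any spot holds `immune_threshold = 5` epithelial cells, one agent per
hour spawns at a uniform random spot.  Agents patrol by uniform random walk,
chase the nearest neoplastic cell within a Chebyshev radius of 3 spots
(wrap-aware; the radius is a model choice — perception is not quantified
biologically), kill at most one neoplastic co-occupant per tick, never touch
physiological cells, and retire after `immune_kill_budget = 5` kills.
Overcrowding mimics hypoxic niches: any spot above `hypoxia_threshold = 5`
loses the uniform excess (cause `hypoxic`), so end-of-tick occupancy never
exceeds the threshold.  Immune agents occupy spots but do not count toward
epithelial crowding.

## Runs, stop conditions, observables

Runs stop at one model year, at TA/differentiated proportion inversion
(strict count inversion), or at 10,000 epithelial cells.  The figures of
interest use the 365-tick year; the hour-resolution default `max_ticks` is
8760 and a `--model-year` preset selects 365.

Observers record per tick: population counts per typology and immune
agents, deaths by cause (physiological, hypoxic, immune, tumoral) plus
exits, and driver-genotype class counts among live cells (dead/exited cells
are excluded from the denominator).  Cumulative surfaces: division events
by layer, per-typology histograms of per-cell division counts, the
cells-per-spot distribution at the tick of maximum total neoplastic
population (pre-adenoma + adenoma + tumoral argmax) with its log-linear
decay slope, and residence-time extremes.  Death-rate series are smoothed
with a 24 h centered moving average.

## Initialization

One cell per spot (2,500), bottom-quarter layers TA, the rest
differentiated.  Each driver gene is independently heterozygous with
probability `p_het` (default 0.5, [1,0]/[0,1] equiprobable).  Ages are
uniform on [0, lifespan) and mitosis clocks uniform on [1, mean]: the crypt
starts at its renewal equilibrium, because a synchronized cohort would
produce artifactual division and death waves in the first days.

## Numerical and design notes

* Determinism: one `random.Random(seed)` stream drives all agent-level
  decisions and one identically seeded numpy generator the mutation draws;
  identical (config, seed) gives bit-identical outputs.
* Replenishment closes the tick rather than opening the next one — the two
  orderings are cyclically identical, but end-of-tick observation then sees
  the full 2,500-cell epithelium.
* `base_prob = 0` with TP53 lost returns probability 0 (the exponent form
  is bypassed rather than raising on log10(0)).
* Degenerate occupancy histograms (no stacking ever) report a NaN decay
  slope rather than fitting one point.
* A cell reaching its lifespan dies on the following tick, so the longest
  possible residence is lifespan + 1 = 121 ticks.

## Known limitations

* The 12 h cycle of KRAS-heterozygous cells is a heritable growth-rate
  advantage, and within a laterally-competing epithelium it slowly enriches
  KRAS heterozygotes above their stem-niche supply frequency (~0.48 per
  heterozygote class by late in a model year, versus 0.25 at the niche;
  APC and TP53 stay at 0.25/0.50).  Keying the fast cycle to the adenoma
  phenotype instead would hold all bands at the niche values but halves the
  homeostatic division rate and with it the ~127 cells/h death rate, so the
  genotype-keyed cycle is retained.
* Because every physiological cell cycles at 24 h, division events are
  nearly uniform in crypt height (~23% in the bottom-quarter TA zone).
  A strongly TA-dominated division profile would require differentiated
  cells not to cycle, which is incompatible with the homeostatic death rate
  above; both cannot hold in this architecture.
* At mutation probability 1e-6 with replication-linked mutation, full APC
  inactivation is a ~0.3-per-year event, so most seeds of a one-year run
  show no neoplastic expansion; the peak physiological-death rate there
  (~129/h) reflects homeostatic fluctuation rather than recurring
  expansions.
* No explicit stem cells, no 3D geometry, no Wnt ligand diffusion, no
  epistasis between drivers, no cytokine fields or immune subtypes; the
  microenvironment is two thresholds and one killer archetype.

## Problem sizes

All shipped analyses are desk-scale: a 2,500-cell crypt, one-year runs of
365 ticks (seconds each), 500-1000-tick physiological runs, and 150-tick
high-mutation runs that grow to ~5,000-10,000 cells.  The acceptance script
uses 5 replicate seeds per stochastic quantity (10 for the high-mutation
growth check).
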