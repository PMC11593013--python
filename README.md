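# cryptsim

Agent-based simulation of colorectal-cancer initiation in a single colonic
crypt, for computational-oncology experiments on how driver-gene mutation
rates and the microenvironment shape the adenoma–carcinoma sequence.

The crypt is an unfolded cylinder: 100 layers × 25 columns of cell-sized
spots with lateral wrap.  Epithelial cell agents are born at the base,
migrate one layer per hour toward the mouth, differentiate as the
beta-catenin gradient (1 at the base, 0 at the mouth) falls below 0.75, and
exit at the top.  Each cell carries APC, KRAS and TP53 as binary allele
pairs plus 50 regulation genes; mutation is rolled per allele at each
division (probability `p`, the scenario dial, 10⁻⁹…10⁻²), with loss of
heterozygosity boosting the second hit tenfold — `P(second hit) =
min(1, 10·p)` — and TP53-null cells gaining 0.5 on the probability exponent
per division.  Genotype determines phenotype:

| genotype                      | typology    | cycle | movement            |
|-------------------------------|-------------|-------|---------------------|
| APC not [1,1]                 | TA / differentiated | 24 h (12 h if KRAS mutant) | up, if free |
| APC [1,1]                     | pre-adenoma | 24 h  | diagonal drift      |
| APC [1,1] + KRAS hit          | adenoma     | 12 h  | diagonal drift      |
| … + TP53 [1,1]                | tumoral     | 10 h  | immobile, divides in all 8 directions |

Dividing physiological cells blocked on both sides eliminate the least-fit
neighbour (fewest divisions, then oldest); neoplastic cells instead stack,
which arms the microenvironment: spots at 5 cells trigger immune killer
agents (1/h, kill budget 5, chase radius 3) and spots above 5 lose the
excess to hypoxic death.  Runs stop after one model year, at
transit-amplifying/differentiated proportion inversion, or at 10,000 cells.

See `docs/methods.md` for the full model description and its limitations.

## Worked example

```
cryptsim run --seed 7 --out out/demo --mutation-prob 1e-3 --model-year
```

prints

```
stopped after 365 ticks (year_elapsed); live=3712 exits=4280
deaths={'hypoxic': 7919, 'immune': 683, 'physiological': 48068, 'tumoral': 14}
populations={'transit_amplifying': 638, 'differentiated': 1830,
             'pre_adenoma': 0, 'adenoma': 2, 'tumoral': 1242}
```

Read: at mutation probability 10⁻³ the crypt survived its model year but is
no longer homeostatic — 1,242 tumoral cells stack in clusters, overcrowding
has killed 7,919 cells (hypoxic niches), immune agents have cleared 683
neoplastic cells, and the physiological death count (~132/h: lifespan
deaths plus mitosis-driven eliminations) still dominates.  The same command
writes tidy CSVs (`populations.csv`, `deaths.csv`, `genotype_freqs.csv`,
`mitosis_hist.csv`, `height_profile.csv`, `occupancy_peak.csv`, a final
grid snapshot and `run_meta.json`) for any downstream plotting.

`cryptsim sweep --probs 1e-9,1e-7,1e-6,1e-5,1e-4,1e-3,1e-2 --replicates 5
--seed 0 --out out/sweep --model-year` runs the full scenario grid.

The library mirrors the CLI:

```python
from cryptsim import SimConfig, StopConfig, run, death_rate_series

cfg = SimConfig(base_prob=1e-9, p_het=0.5, seed=1, stop=StopConfig(max_ticks=500))
result = run(cfg)
rate = death_rate_series(result.metrics.deaths(), window=24)
print(round(rate.iloc[150:].mean(), 1))   # 127.4 cells/h homeostatic death rate
```

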