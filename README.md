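# swarmforage

Simulation toolkit for studying how **task partitioning** — a division
of labor in which a sequential task is split between sets of
individuals — can evolve in groups of identical foraging robots.

The scenario mirrors leafcutter-ant foraging: a team of robots must
retrieve items from a **source** area back to a **nest**, across a
middle region that is either flat or an 8° **slope**. Climbing the
slope is slow (0.015 m/s vs 0.15 m/s on flat ground), descending is
fast (0.23 m/s), and a free item dropped on the slope slides down at
1 m/s until it is stopped in a **cache** at the slope's foot. The slope
therefore rewards splitting the task between *droppers* (collect at the
source, drop into the slope, let gravity transport) and *collectors*
(ferry cache items to the nest), while the flat environment favors
*generalists* doing the whole task alone.

The package provides:

* a deterministic, seeded kinematic simulator (numba-accelerated) for
  teams of differential-drive robots with phototaxis, anti-phototaxis
  and random-walk primitives, obstacle avoidance, item pickup/drop,
  gravity transport and source replenishment;
* a probabilistic **rule-based controller** formalism
  `R = {R_i}`, `R_i = P_i × B_i × A_i`: ordered rules with boolean
  preconditions `P_i`, a low-level-behavior gate `B_i`, and actions
  `A_i` each executed with probability `p_l`;
* hand-coded dropper / collector / generalist strategies (one shared
  8-rule set; roles differ only in two initial memory bits);
* exhaustive **fitness-landscape** search over all strategy mixes of a
  team, with the discrete steepest-ascent phase portrait on the
  composition simplex;
* **grammatical evolution** of controllers from scratch: integer-codon
  genotypes mapped through an EBNF grammar to rule sets, evolved with
  roulette-wheel selection, single-point crossover (p = 0.3), per-codon
  mutation (p = 0.05) and 5 % elitism, selecting only on group
  performance (items delivered);
* metrics and figures: group fitness, **degree of task specialization**
  (fraction of delivered items handled by more than one robot), mean
  linear speed, robot-density maps, cache-size series, fitness
  regression, and 4→20-robot scalability ratios.

## Worked example

Exhaustive landscape search over all fifteen 4-robot strategy mixes in
the sloped arena (10 seeded 5,000 s episodes per mix):

```bash
swarmforage landscape --arena sloped --team 4 --reps 10 --T 5000 --seed 1 --out ls-sloped
```

prints

```
argmax: (2, 2, 0)  mean fitness 244.0
```

i.e. the optimal composition is **2 droppers + 2 collectors + 0
generalists**, delivering on average 244 items in 5,000 s. The same
search in the flat arena (`--arena flat`) prints

```
argmax: (0, 0, 4)  mean fitness 174.0
```

— all-generalist foraging wins on flat ground, and the partitioned
sloped optimum outperforms the flat optimum because gravity does part
of the transport. `ls-sloped/landscape.png` shows the ternary fitness
landscape with its phase portrait (every arrow chain runs to the single
global optimum).

Evolving a controller from scratch at desk scale (population 30, 200
generations, 2 × 2,000 s evaluations; a few minutes):

```bash
swarmforage evolve --arena sloped --seed 0 --out evo0
```

```
best-ever fitness 48.5, final specialization 0.82
```

Selection saw only the delivered-item count, yet the best evolved
controller retrieves 82 % of its items through the hands of more than
one robot — self-organized task partitioning, with role allocation
driven stigmergically by the cache.

Single episodes, trace CSVs and figures:

```bash
swarmforage simulate --arena sloped --controller 2,2,0 --robots 4 --T 5000 --seed 7 --trace run7
swarmforage plot --what density --traces run7 --out density.png
swarmforage export-strategy --role dropper
```

## Layout

| module | contents |
| --- | --- |
| `swarmforage.world` | arena geometry, world state, scripted fixture traces |
| `swarmforage.sim` | episode simulator (kernel in `_engine`) |
| `swarmforage.rules` | rule formalism, parser, behavior primitives |
| `swarmforage.strategies` | hand-coded dropper/collector/generalist |
| `swarmforage.landscape` | exhaustive mix search, phase portrait |
| `swarmforage.evolve` | grammar, genotype mapping, genetic algorithm |
| `swarmforage.metrics` | fitness, specialization, speed, density, scaling |
| `swarmforage.cli` | `swarmforage` command, configs, pipelines |

See `docs/methods.md` for the model description, parameter rationale
and known limitations.
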