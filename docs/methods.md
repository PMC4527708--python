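# Model and methods

## The task and the world model

A team of identical robots forages in a rectangular corridor
(9.75 m × 1.75 m at base scale) divided along its long axis into four
zones: `nest | cache | slope | source`. Items must be taken from the
source and released in the nest; each delivered item counts one unit of
group fitness. Five items are always present in the source: whenever
one is picked up there, a replacement appears at a uniformly random
source position (the source models an effectively unlimited supply).

In the **sloped** environment the middle zone is an 8° incline: robots
climb at ≤ 0.015 m/s, descend at ≤ 0.23 m/s, and move at ≤ 0.15 m/s
elsewhere. An item released on the slope slides downhill at 1 m/s until
it crosses the slope foot, where friction and the pile stop it just
inside the cache (with a small lateral scatter). The **flat**
environment has the same footprint and zone markings but uniform speeds
and no sliding. A light beacon far beyond the source end makes
navigation trivial to express: phototaxis is "+x", anti-phototaxis
"−x".

Zone segment lengths are not dictated by the scenario beyond the total;
the defaults are nest 1.5 m, cache 2.5 m, slope 3.75 m, source 2.0 m.
They were calibrated (and are overridable in the arena config) so that
the slope climb (~250 s) dominates a solo round trip and the two
specialist subtasks — searching the source versus shuttling between
cache and nest — take comparable time. That balance is what makes an
even specialist mix optimal on the incline; with a strongly asymmetric
split, exhaustive search finds lopsided optima instead.

`make_arena(environment, scale)` multiplies length and width by
`scale`; the source item count grows with the source area
(`round(5·scale²)`) so item *density*, and hence search effort per
robot, is scale-invariant.

## Robot motion

Robots are discs of radius 0.085 m (a foot-bot footprint) with a
unicycle kinematic model integrated at `dt = 0.1 s`. Each control step
a robot's active low-level behavior proposes a desired direction:

* `PHOTOTAXIS` — toward the light (+x); `ANTI_PHOTOTAXIS` — away;
* `RANDOM_WALK` — a piecewise-constant heading, resampled uniformly on
  [0, 2π) after a dwell drawn uniformly from [2 s, 10 s].

Obstacle avoidance is always on: linear repulsion from robots within
0.35 m and walls within 0.2 m, rotated by +0.4 rad so that a blocked
robot slides sideways along the obstruction instead of stalling
(Braitenberg-style turn-away). The blended steering target is tracked
with a bounded turn rate (1.5 rad/s), and the forward speed is the
zone/direction cap scaled by `max(0, cos(heading error))` — a robot
commanded to reverse rotates roughly in place, as a differential-drive
platform does. Without that scaling, a dropper reversing at the slope
top overshoots ~0.4 m downhill at 0.23 m/s and pays a ~25 s climb back
every cycle, which erases the cost structure the slope exists to
create. Residual body contacts are resolved by sliding the movement
candidate off the neighbor; a robot never ends a step overlapping
another.

Items are physical cylinders: their centers keep 0.1 m from arena
walls (spawn and cache-stop positions). Without this margin, wall-flush
items sit behind the wall-avoidance strip, survive selectively, and
stall search for hundreds of seconds. Items sliding at 1 m/s are not
eligible for pickup (≈ 6× robot speed; a dropped item would otherwise
be re-grasped on the next control tick before it can escape downhill).
Pickup reach is 0.15 m from the robot center; lowest robot id wins a
contested pickup (robots act in id order within a step).

## Controllers

A controller is an ordered rule set `R = {R_i}`, `R_i = P_i × B_i ×
A_i`. Preconditions are required boolean values over the four zone
indicators, `carrying`, `want_pickup`, and two bounded memory counters
`M1`, `M2` (read as "non-zero"; writable by set/increment/decrement
actions). A rule fires when all preconditions hold *and* the robot's
current behavior is in `B_i`; each action then executes independently
with its probability `p_l`. Rules are scanned in order once per control
step; behavior and memory writes are visible to later rules in the same
scan, while pickup/drop are attempted against the world after the scan.
With all `p_l = 1` the controller is deterministic given its percepts.

The hand-coded dropper, collector and generalist share one 8-rule set
and differ only in the initial values of two named memories, STAY_UP
and STAY_DOWN (aliases of M1/M2); the rule subsets each role actually
exercises are droppers R1, R4–R6; collectors R2–R3, R5, R7–R8;
generalists R1, R4–R5, R7–R8 (see `swarmforage/strategies.py` for the
rules and their gating). One deliberate detail: the source-search rule
(R4) switches into random walk with probability 0.02 per scan rather
than deterministically, so phototaxis first carries the robot into the
zone interior; an immediate switch makes robots dither at the zone
boundary and roughly doubles the search time.

## Fitness landscape over strategy mixes

For a team of *n* robots the composition space over the three roles has
`C(n+2,2)` mixes (15 for n = 4). Every mix is evaluated with replicate
seeded episodes; replicate *r* of every mix shares a seed derived from
`(base_seed, r)`, so mixes are compared under common random numbers.
The phase portrait assigns each mix the one-robot reassignment with the
greatest mean-fitness gain (zero at local optima) — the discrete
analogue of a selection gradient on the simplex.

## Grammatical evolution

Genotypes are variable-length strings of 8-bit codons. The phenotype is
derived by standard grammatical evolution: expand the leftmost
nonterminal choosing alternative `codon mod n_alternatives`,
single-alternative nonterminals consume no codon, the codon stream
wraps at most 3 times, and an incomplete derivation is an invalid
phenotype with fitness 0.

The grammar generates exactly the rule formalism above. Its shape
embodies several deliberate choices:

* the genotype's first production selects the robots' initial behavior
  (`INIT`): the generative encoding specifies the whole controller.
  With a fixed random-walk start, the asymmetric slope speeds make the
  incline a one-way barrier (uphill legs crawl at 0.015 m/s, downhill
  legs race at 0.23 m/s), no random controller ever reaches the source
  and delivers, and the search has no gradient at any population size
  (measured: 0 deliveries in 4,000 random controllers);
* action probabilities come from a 20-value log-spaced grid on
  [0.001, 1]: rules are scanned at 10 Hz, so meaningful event rates
  span three decades, and transport-scale timing (release after seconds
  of carrying) needs per-scan probabilities well below the 0.05 floor
  of a linear grid;
* rule lists continue with probability 4/5 (mean ≈ 5 rules, matching
  the 4–11 rules seen in competent evolved foragers) and the two item
  actions carry the same total alphabet weight as the three behavior
  switches. Together these raise the chance that a random controller
  contains a complete forage-and-return chain from ~2.6 × 10⁻⁴ to
  ~1.9 × 10⁻³ — findable by a desk-scale population.

The genetic algorithm is generational with 5 % elitism,
roulette-wheel selection proportional to fitness (uniform fallback when
every fitness is zero, as in the earliest generations), single-point
variable-length crossover with probability 0.3, and per-codon uniform
mutation with probability 0.05. Fitness is the mean delivered-item
count of a homogeneous team over independent seeded evaluations;
nothing else is rewarded. Per-genotype evaluation seeds derive from
(run seed, generation, slot), so results are independent of evaluation
order and parallel scheduling. The best controller of each generation
is post-evaluated (with event recording) for specialization degree and
mean speed; post-evaluation is skipped while the best fitness is zero,
where both metrics are undefined.

Full-scale settings (population 100, 2,000 generations, 3 × 5,000 s
evaluations) are shipped as `ga_paper.yaml` for cluster use. The
desk-scale profile (population 30, 200 generations, 2 × 2,000 s) keeps
every mechanism and completes in minutes; it trades discovery
probability per run, not the nature of the dynamics.

## Metrics

* **Fitness** — deliver-event count of a trace.
* **Degree of task specialization** — fraction of delivered items whose
  pickup events involve ≥ 2 distinct robots. Gravity transport adds no
  handler; repeated pickups by one robot count once; undefined (NaN)
  when nothing was delivered. Being a proportion, it is only
  informative when the delivered count is non-trivial: a
  barely-functional controller that relays three items hand-to-hand
  reads 1.0, which says nothing about an evolved division of labor.
* **Mean linear speed** — mean |Δx|/Δt over robots and 1 s snapshot
  intervals, as a percentage of the nominal 0.15 m/s flat cap (the
  0.23 m/s downhill coast is a transient aid, not the reference).
* **Density maps** — column-normalized occupancy over (x, time).
* **Fitness regression** — OLS of per-run fitness on specialization and
  speed (statsmodels), with degenerate-predictor flagging.
* **Scalability ratio** — mean fitness of a controller (or
  proportionally scaled mix) at 20 robots in a 5×-scaled arena over its
  4-robot mean, seeds shared between the two team sizes.

## What the synthetic scenarios do and do not show

All experiments here are pure simulation; the world model *is* the data
generator. It reproduces the study conditions — geometry, the stated
speeds, gravity transport, replenishment — with a kinematic (not
dynamic) robot model: no wheel slip, sensing noise, battery model, or
item–robot collisions, and the slope acts only through speed caps and
item sliding. Passing tests therefore demonstrate properties of the
model class (structural optima, direction of environment effects,
evolvability of partitioning), not quantitative predictions for
physical robots; absolute fitness values shift with zone geometry and
avoidance details, which is why the test surface is structural.

## Numerical choices and degenerate inputs

Control/integration step 0.1 s; episode state is float64; the
simulation stream is a 64-bit xorshift\* generator carried in the world
state, implemented identically in the kernel and in Python so that
stepping one tick at a time and running a batched episode are bitwise
identical. Argmax ties in the landscape resolve to the first mix in
enumeration order; the phase portrait requires a strict improvement to
point anywhere. Zero-fitness populations select uniformly. A
zero-replicate or single-replicate evaluation flags its undefined SD
rather than guessing. Non-finite robot state aborts the episode with a
`SimulationFault`. Item-array capacity grows by deterministic restart
(same seed, larger buffers), so pathological drop/pickup loops cannot
overflow or bias results.

## Known limitations

* The 8-rule reconstruction of the hand-coded strategies reproduces the
  published behavioral contracts, not any byte-level original.
* The evolution grammar is this package's own design within the stated
  formalism; different grammar ergonomics shift the bootstrap
  probability of de-novo runs considerably (see above).
* Desk-scale evolution succeeds in a minority of seeds by design
  (5 runs at population 30 explore ~6,000 genotypes versus ~600,000 at
  full scale); individual seeds may spend their entire budget in the
  zero-fitness phase.
* Scaling an arena in both dimensions lengthens every travel leg
  ~linearly in `scale`, while team throughput grows with robot count;
  see the scalability discussion in the test suite for where the
  linear-scaling expectation holds and where geometry erodes it.
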