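# Desk-scale evolutionary settings: completes in minutes on one CPU
# while preserving the qualitative dynamics (see docs/methods.md).
kind: evolution
population_size: 30
team_size: 4
generations: 200
evaluations: 2
T: 2000.0
dt: 0.1
crossover_prob: 0.3
mutation_prob: 0.05
elitism: 0.05
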