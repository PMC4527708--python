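# Full-scale evolutionary settings (cluster-sized).
kind: evolution
population_size: 100
team_size: 4
generations: 2000
evaluations: 3
T: 5000.0
dt: 0.1
crossover_prob: 0.3
mutation_prob: 0.05
elitism: 0.05
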