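label: founder100_rec2000
burnin_years: 500000
mainland_capacity: 50000
events:
- time: 7000
  population: island
  carrying_capacity: 100
  kind: found_from_mainland
- time: 6900
  population: island
  carrying_capacity: 2000
  kind: set_capacity
- time: 1200
  population: island
  carrying_capacity: 20000
  kind: set_capacity
- time: 200
  population: island
  carrying_capacity: 1800
  kind: set_capacity
- time: 100
  population: island
  carrying_capacity: 20000
  kind: set_capacity
life_history:
  first_repro_age: 1
  max_repro_age: 13
  male_breeding_fraction: 0.5
  litter_probs:
  - 0.5019607843137255
  - 0.25098039215686274
  - 0.12549019607843137
  - 0.06274509803921569
  - 0.03137254901960784
  - 0.01568627450980392
  - 0.00784313725490196
  - 0.00392156862745098
  max_longevity: 16
  age_mortality:
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.74
  - 1.0
  generation_time: 6.0
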