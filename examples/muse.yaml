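outcomes:
- kind: continuous
  effect_obs: 0.88
  sd: 4.242640687119285
  name: SLEDAI
- kind: continuous
  effect_obs: 0.38
  sd: 0.5916079783099616
  name: PGA
- kind: ordinal
  prob_T: 0.97
  prob_C: 0.95
  effect_latent: 0.24
  n_levels: 5
  name: BILAG
- kind: binary
  prob_T: 0.54
  prob_C: 0.38
  effect_latent: 0.4
  name: Taper
corr:
- - 1.0
  - 0.448
  - 0.521
  - 0.003
- - 0.448
  - 1.0
  - 0.448
  - -0.031
- - 0.521
  - 0.448
  - 1.0
  - 0.066
- - 0.003
  - -0.031
  - 0.066
  - 1.0
alloc_ratio: 1.0
alpha: 0.025
target_power: 0.8
adjustment: none
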