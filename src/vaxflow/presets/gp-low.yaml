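# Published gp preset, low staffing capacity.
site: gp
level: low
reps: 20
seed: 0
no_show_prob: 0.02
adverse_prob: 0.02
noise: {family: normal, mean: -10.0, sd: 5.0}
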