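# Default synthetic analysis: 20 years on a 6x6 pixel grid.
mode = "synthetic"
bloom_threshold = 0.65
driver = "dnhf"

[simulation]
seed = 42
n_years = 20
n_lat = 6
n_lon = 6
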