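[population]
n_cells = 200
lifetime_mean = 2.593
lifetime_std = 0.13
intensity_mean = 2000.0
arrival_rate = 5.0
background_rate = 2000.0
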