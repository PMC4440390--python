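[population]
n_cells = 200
lifetime_mean = 2.038
lifetime_std = 0.18
intensity_mean = 2000.0
arrival_rate = 5.0
background_rate = 2000.0

[acquisition]
sync_period = 12.5
micro_window = 12.5
bin_width = 20.0
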