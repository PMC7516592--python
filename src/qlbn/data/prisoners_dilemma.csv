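label,cond_given_first,cond_given_not_first,observed_sub,classical_printed,sample_size,modelled_outcome
(a) Tversky and Shafir,0.84,0.97,0.63,0.9050,80,not_y
(b) Li and Taplin,0.77,0.82,0.72,0.7950,30,not_y
(c) Busemeyer et al.,0.84,0.91,0.66,0.8750,88,not_y
(d) Hristova and Grinberg,0.93,0.97,0.88,0.9500,20,not_y
(e) Average,0.85,0.92,0.72,0.8813,54,not_y
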