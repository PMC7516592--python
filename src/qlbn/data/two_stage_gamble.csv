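label,cond_given_first,cond_given_not_first,observed_sub,classical_printed,sample_size,modelled_outcome
(i) Tversky and Shafir,0.69,0.58,0.37,0.6350,98,y
(ii) Kuhberger et al.,0.72,0.47,0.48,0.5950,135,y
(iii) Lambdin and Burdsal,0.63,0.45,0.41,0.5400,57,y
(iv) Average,0.68,0.50,0.42,0.5900,96,y
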