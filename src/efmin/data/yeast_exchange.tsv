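# Correlation coefficients between predicted and measured exchange fluxes,
# S. cerevisiae chemostat cultures at two glucose uptake rates (mmol/(gDW.h)).
uptake_rate	E-Fmin	GIMME	FBA (classical)	FBA (flux min)	E-Flux	Lee et al.	iMAT
16.5	0.99	0.64	0.64	0.64	0.99	0.99	0.63
11.0	0.98	0.83	0.83	0.83	0.97	0.93	0.83
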