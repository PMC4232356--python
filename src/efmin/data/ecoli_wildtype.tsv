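# Correlation coefficients between predicted and 13C-MFA intracellular fluxes,
# wild-type E. coli chemostat cultures at five dilution rates (1/h).
# Entries censored below detection ("<0.01") are stored at the interval
# midpoint 0.005; any value in (0, 0.01) gives the same ranks.
dilution_rate	E-Fmin	GIMME	FBA (classical)	FBA (flux min)	E-Flux	Lee et al.	iMAT	iMAT (outliers removed)
0.1	0.91	0.86	0.005	0.94	0.46	0.35	0.005	0.88
0.2	0.88	0.86	0.04	0.93	0.40	0.40	0.04	0.85
0.4	0.91	0.91	0.05	0.97	0.66	0.43	0.05	0.91
0.5	0.94	0.86	0.05	0.95	0.77	0.43	0.05	0.85
0.7	0.92	0.83	0.08	0.93	0.84	0.21	0.08	0.90
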