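# Correlation coefficients between predicted and 13C-MFA intracellular fluxes,
# E. coli single-gene knockout strains at dilution rate 0.2 1/h.
knockout	E-Fmin	GIMME	FBA (classical)	FBA (flux min)	E-Flux	Lee et al.	iMAT (outliers removed)
galM	0.90	0.85	0.01	0.93	0.40	0.36	0.87
glk	0.84	0.82	0.08	0.91	0.52	0.37	0.83
pgm	0.87	0.82	0.06	0.93	0.72	0.38	0.85
pgi	0.93	0.84	-0.03	0.90	0.56	0.23	0.93
pfkA	0.87	0.86	0.05	0.94	0.70	0.44	0.84
pfkB	0.93	0.88	-0.01	0.95	0.58	0.35	0.91
fbp	0.88	0.85	-0.01	0.92	0.47	0.42	0.82
fbaB	0.89	0.87	0.03	0.95	0.53	0.41	0.87
gapC	0.91	0.86	-0.01	0.93	0.52	0.36	0.87
gpmA	0.87	0.84	0.05	0.94	0.53	0.43	0.85
gpmB	0.83	0.80	0.09	0.90	0.55	0.36	0.83
pykA	0.89	0.86	0.03	0.94	0.56	0.42	0.86
pykF	0.94	0.90	-0.03	0.95	0.59	0.34	0.91
ppsA	0.87	0.86	0.08	0.94	0.35	0.38	0.89
zwf	0.85	0.90	0.04	0.90	0.59	0.38	0.82
pgl	0.88	0.85	0.05	0.93	0.72	0.39	0.85
gnd	0.84	0.89	0.07	0.90	0.46	0.36	0.83
rpe	0.87	0.79	0.07	0.89	0.64	0.31	0.82
rpiA	0.86	0.80	0.06	0.90	0.73	0.28	0.84
rpiB	0.85	0.79	0.09	0.90	0.44	0.22	0.88
tktA	0.79	0.73	0.14	0.86	0.30	0.25	0.82
tktB	0.84	0.83	0.09	0.93	0.49	0.41	0.84
talA	0.86	0.85	0.08	0.93	0.53	0.43	0.84
talB	0.85	0.84	0.08	0.93	0.36	0.40	0.84
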