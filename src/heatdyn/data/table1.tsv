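location	mutation	repeat	element	ddg_kcal_mol	pathogenicity
regulatory subunit interface	M179H	4	helix 2	1.52	0.71
regulatory subunit interface	R182T	5	helix 2	1.46	0.77
regulatory subunit interface	S255F	6	loop 1	1.47	0.86
regulatory subunit interface	W256H	6	helix 2	2.08	0.82
catalytic subunit interface	W416F	11	helix 2	1.23	0.82
catalytic subunit interface	R497T	13	helix 2	1.34	0.81
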