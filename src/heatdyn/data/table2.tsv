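mutation	pathogenicity	mean_end_to_end_A	sd_end_to_end_A	corner_frequency_hz	corner_frequency_sd_hz	normalized_rmsd	normalized_rmsd_sd
S323L	0.24	70.3	9.4	122.82	5.4	0.0018	0.0009
F502W	0.36	70.4	9.9	45.07	2.0	0.0019	0.0007
WT	0	66.2	9.8	24.66	2.9	0.0021	0.0009
E375D	0.20	68.4	8.9	25.75	5.9	0.0030	0.0007
Y168V	0.18	64.6	11.2	20.97	4.3	0.0033	0.0006
L197V	0.04	67.2	9.7	16.78	1.2	0.0067	0.0015
D315E	0.03	58.2	15.6	15.99	3.1	0.0099	0.0028
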