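type_name	epsilon	sigma	charge	solv_sigma	vdw_radius
NB	0.200	3.30	-0.47	-0.060	1.85
CQ	0.110	3.70	0.51	0.012	2.00
OB	0.120	3.00	-0.51	-0.060	1.70
CA1	0.020	4.00	0.07	0.012	2.27
CH1	0.032	4.05	-0.09	0.012	2.27
CH2	0.056	3.90	-0.18	0.012	2.17
CH3	0.078	3.75	-0.27	0.012	2.06
CAR	0.070	3.55	-0.115	0.012	1.99
CRP	0.090	3.60	0.30	0.012	1.98
NP	0.200	3.30	-0.60	-0.100	1.85
NC	0.200	3.30	-0.30	-0.120	1.85
OP	0.152	3.15	-0.66	-0.100	1.77
OC	0.120	3.00	-0.76	-0.120	1.70
SM	0.450	3.95	-0.09	-0.0045	2.00
HVR	0.022	2.35	0.09	0.000	1.32
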