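segment	layer	mass_kg	C_J_per_degC	QB_W	BF_basal_l_per_s	TC_out_W_per_degC	area_m2
head	core	3.0	11550.0	16.4	0.0125	1.2	0.0
head	muscle	0.4	1507.0	0.15	0.0002	9.9	0.0
head	fat	0.85	2133.0	0.1	0.0002	12.075	0.0
head	skin	0.65	2392.0	0.1	0.0003	0.0	0.132
trunk	core	18.0	63000.0	52.0	0.058	3.0	0.0
trunk	muscle	12.0	45216.0	5.0	0.0035	4.5	0.0
trunk	fat	6.5	16315.0	0.6	0.0008	13.5	0.0
trunk	skin	2.4	8832.0	0.3	0.00055	0.0	0.68
arms	core	1.5	3750.0	0.4	0.0008	1.875	0.0
arms	muscle	3.5	13188.0	1.2	0.0012	3.75	0.0
arms	fat	1.0	2510.0	0.1	0.0003	7.5	0.0
arms	skin	0.8	2944.0	0.1	0.000225	0.0	0.254
hands	core	0.3	750.0	0.05	0.0002	1.125	0.0
hands	muscle	0.2	754.0	0.05	0.0002	2.25	0.0
hands	fat	0.2	502.0	0.02	0.0001	6.0	0.0
hands	skin	0.4	1472.0	0.05	0.000175	0.0	0.095
legs	core	4.0	10000.0	1.0	0.0015	3.0	0.0
legs	muscle	10.0	37680.0	3.5	0.003	6.0	0.0
legs	fat	3.0	7530.0	0.25	0.0006	12.0	0.0
legs	skin	1.5	5520.0	0.2	0.0004	0.0	0.604
feet	core	0.35	875.0	0.1	0.0002	1.5	0.0
feet	muscle	0.25	942.0	0.1	0.0002	3.0	0.0
feet	fat	0.25	628.0	0.05	0.0001	7.5	0.0
feet	skin	0.45	1656.0	0.1	0.000175	0.0	0.125
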