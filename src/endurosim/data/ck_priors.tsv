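name	prior_mean	prior_sd_rel	units
mm_vmax	60000.0	0.3	uM/s
mm_k_adp	135.0	0.2	uM
mm_k_pcr	4600.0	0.2	uM
mm_k_atp	3500.0	0.2	uM
mm_k_cr	16000.0	0.2	uM
mi_vmax	10000.0	0.3	uM/s
mi_k_adp	204.8	0.2	uM
mi_k_pcr	1600.0	0.2	uM
mi_k_atp	750.0	0.2	uM
mi_k_cr	5200.0	0.2	uM
ox_vmax	1600.0	1.0	uM/s
ox_k_adp	40.0	1.0	uM
ox_k_pi	800.0	1.0	uM
ps_atp	6.0	1.0	1/s
ps_adp	6.0	1.0	1/s
ps_pcr	50.0	1.0	1/s
ps_cr	50.0	1.0	1/s
ps_pi	50.0	1.0	1/s
v_cyt	0.9375	0.05	l/l
v_ims	0.0625	0.1	l/l
total_creatine	42500.0	0.1	uM
total_adenine	8230.0	0.1	uM
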