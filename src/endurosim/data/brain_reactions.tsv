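reaction_id	equation	reversible	subsystem
EX_glc	glc__D_e <->	True	exchange
EX_lac	lac__L_e <->	True	exchange
EX_o2	o2_e <->	True	exchange
EX_co2	co2_e <->	True	exchange
EX_hdca	hdca_e <->	True	exchange
EX_ala	ala__L_e <->	True	exchange
GLCt1	glc__D_e --> glc__D_c	False	transport
LACt	lac__L_e <-> lac__L_c	True	transport
O2t	o2_e --> o2_c	False	transport
O2tm	o2_c --> o2_m	False	transport
CO2tm	co2_m --> co2_c	False	transport
CO2t	co2_c --> co2_e	False	transport
HEX1	glc__D_c + atp_c --> g6p_c + adp_c	False	glycolysis
PGI	g6p_c <-> f6p_c	True	glycolysis
PFK	f6p_c + atp_c --> fdp_c + adp_c	False	glycolysis
FBA	fdp_c <-> dhap_c + g3p_c	True	glycolysis
TPI	dhap_c <-> g3p_c	True	glycolysis
GAPD	g3p_c + nad_c + pi_c <-> 13dpg_c + nadh_c	True	glycolysis
PGK	13dpg_c + adp_c <-> 3pg_c + atp_c	True	glycolysis
PGM	3pg_c <-> 2pg_c	True	glycolysis
ENO	2pg_c <-> pep_c	True	glycolysis
PYK	pep_c + adp_c --> pyr_c + atp_c	False	glycolysis
LDH_L	pyr_c + nadh_c <-> lac__L_c + nad_c	True	glycolysis
G6PDH2r	g6p_c + nadp_c --> 6pgl_c + nadph_c	False	ppp
PGL	6pgl_c --> 6pgc_c	False	ppp
GND	6pgc_c + nadp_c --> ru5p__D_c + co2_c + nadph_c	False	ppp
RPI	ru5p__D_c <-> r5p_c	True	ppp
RPE	ru5p__D_c <-> xu5p__D_c	True	ppp
TKT1	xu5p__D_c + r5p_c <-> s7p_c + g3p_c	True	ppp
TALA	s7p_c + g3p_c <-> e4p_c + f6p_c	True	ppp
TKT2	xu5p__D_c + e4p_c <-> f6p_c + g3p_c	True	ppp
PYRt2m	pyr_c --> pyr_m	False	transport
PDHm	pyr_m + coa_m + nad_m --> accoa_m + co2_m + nadh_m	False	tca
CSm	accoa_m + oaa_m --> cit_m + coa_m	False	tca
ACONTm	cit_m <-> icit_m	True	tca
ICDHxm	icit_m + nad_m --> akg_m + co2_m + nadh_m	False	tca
AKGDm	akg_m + coa_m + nad_m --> succoa_m + co2_m + nadh_m	False	tca
SUCOASm	succoa_m + adp_m + pi_m <-> succ_m + coa_m + atp_m	True	tca
SUCD1m	succ_m + fad_m <-> fum_m + fadh2_m	True	tca
FUMm	fum_m <-> mal__L_m	True	tca
MDHm	mal__L_m + nad_m <-> oaa_m + nadh_m	True	tca
ETCNADH	nadh_m + 0.5 o2_m --> nad_m + 10 hpmf_m	False	oxphos
ETCFADH2	fadh2_m + 0.5 o2_m --> fad_m + 6 hpmf_m	False	oxphos
ATPS4m	4.8275862069 hpmf_m + adp_m + pi_m --> atp_m	False	oxphos
ATPtm	atp_m + adp_c --> atp_c + adp_m	False	transport
PIt2m	pi_c --> pi_m	False	transport
ATPM	atp_c --> adp_c + pi_c	False	maintenance
MDH	oaa_c + nadh_c <-> mal__L_c + nad_c	True	shuttle
AKGMALtm	mal__L_c + akg_m <-> mal__L_m + akg_c	True	shuttle
ASPTA	asp__L_c + akg_c <-> oaa_c + glu__L_c	True	shuttle
ASPTAm	oaa_m + glu__L_m <-> asp__L_m + akg_m	True	shuttle
ASPGLUm	asp__L_m + glu__L_c <-> asp__L_c + glu__L_m	True	shuttle
GPD	dhap_c + nadh_c <-> glyc3p_c + nad_c	True	shuttle
G3PDm	glyc3p_c + fad_m --> dhap_c + fadh2_m	False	shuttle
CITtam	cit_m + mal__L_c <-> cit_c + mal__L_m	True	transport
ACITL	cit_c + atp_c + coa_c --> accoa_c + oaa_c + adp_c + pi_c	False	fas
FAS160	8 accoa_c + 14 nadph_c + 7 atp_c --> hdca_c + 8 coa_c + 14 nadp_c + 7 adp_c + 7 pi_c	False	fas
HDCAt	hdca_c --> hdca_e	False	transport
ALATA_L	pyr_c + glu__L_c <-> ala__L_c + akg_c	True	amino
ALAt	ala__L_c --> ala__L_e	False	transport
GLUDC	glu__L_c --> gaba_c + co2_c	False	amino
GABAtm	gaba_c --> gaba_m	False	transport
ABTArm	gaba_m + akg_m --> sucsal_m + glu__L_m	False	amino
SSALxm	sucsal_m + nad_m --> succ_m + nadh_m	False	amino
GLUtm	glu__L_c <-> glu__L_m	True	transport
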