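metabolite	C	N	P
glc__D	6	0	0
g6p	6	0	1
f6p	6	0	1
fdp	6	0	2
dhap	3	0	1
g3p	3	0	1
13dpg	3	0	2
3pg	3	0	1
2pg	3	0	1
pep	3	0	1
pyr	3	0	0
lac__L	3	0	0
6pgl	6	0	1
6pgc	6	0	1
ru5p__D	5	0	1
r5p	5	0	1
xu5p__D	5	0	1
s7p	7	0	1
e4p	4	0	1
atp	10	5	3
adp	10	5	2
nad	21	7	2
nadh	21	7	2
nadp	21	7	3
nadph	21	7	3
fad	27	9	2
fadh2	27	9	2
coa	21	7	3
accoa	23	7	3
cit	6	0	0
icit	6	0	0
akg	5	0	0
succoa	25	7	3
succ	4	0	0
fum	4	0	0
mal__L	4	0	0
oaa	4	0	0
co2	1	0	0
o2	0	0	0
pi	0	0	1
glu__L	5	1	0
asp__L	4	1	0
ala__L	3	1	0
gaba	4	1	0
sucsal	4	0	0
hdca	16	0	0
glyc3p	3	0	1
hpmf	0	0	0
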