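# Default chemical-shift statistics: residue_type atom_name mean_ppm sd_ppm
# Typical backbone and beta-proton averages over assigned proteins.
# GLY has no CB/HB; PRO has no amide H.
ALA	H	8.19	0.60
ALA	HA	4.26	0.44
ALA	HB	1.35	0.26
ALA	N	123.2	3.5
ALA	CA	53.1	2.0
ALA	CB	19.0	1.8
ALA	C	177.7	2.1
ARG	H	8.24	0.61
ARG	HA	4.30	0.46
ARG	HB	1.79	0.27
ARG	N	120.8	3.7
ARG	CA	56.8	2.3
ARG	CB	30.7	1.8
ARG	C	176.4	2.0
ASN	H	8.35	0.63
ASN	HA	4.67	0.36
ASN	HB	2.81	0.33
ASN	N	118.9	4.0
ASN	CA	53.5	1.9
ASN	CB	38.7	1.7
ASN	C	175.2	1.8
ASP	H	8.31	0.58
ASP	HA	4.60	0.31
ASP	HB	2.72	0.29
ASP	N	120.6	3.9
ASP	CA	54.7	2.0
ASP	CB	40.9	1.6
ASP	C	176.4	1.7
CYS	H	8.38	0.66
CYS	HA	4.69	0.57
CYS	HB	2.95	0.45
CYS	N	120.1	4.6
CYS	CA	58.2	3.3
CYS	CB	32.8	6.1
CYS	C	174.8	2.0
GLN	H	8.22	0.59
GLN	HA	4.27	0.44
GLN	HB	2.05	0.26
GLN	N	119.9	3.6
GLN	CA	56.6	2.2
GLN	CB	29.2	1.8
GLN	C	176.3	2.0
GLU	H	8.33	0.60
GLU	HA	4.25	0.41
GLU	HB	2.03	0.23
GLU	N	120.7	3.5
GLU	CA	57.3	2.1
GLU	CB	30.0	1.7
GLU	C	176.9	2.0
GLY	H	8.33	0.64
GLY	HA	3.97	0.37
GLY	N	109.7	3.9
GLY	CA	45.4	1.3
GLY	C	174.0	1.8
HIS	H	8.25	0.68
HIS	HA	4.61	0.43
HIS	HB	3.11	0.38
HIS	N	119.6	4.0
HIS	CA	56.5	2.3
HIS	CB	30.2	2.1
HIS	C	175.3	2.0
ILE	H	8.26	0.69
ILE	HA	4.17	0.57
ILE	HB	1.78	0.29
ILE	N	121.5	4.3
ILE	CA	61.6	2.7
ILE	CB	38.6	2.0
ILE	C	175.9	1.9
LEU	H	8.22	0.65
LEU	HA	4.32	0.47
LEU	HB	1.62	0.34
LEU	N	121.9	3.9
LEU	CA	55.6	2.1
LEU	CB	42.3	1.9
LEU	C	177.0	2.0
LYS	H	8.25	0.61
LYS	HA	4.26	0.44
LYS	HB	1.78	0.25
LYS	N	121.0	3.8
LYS	CA	56.9	2.2
LYS	CB	32.8	1.8
LYS	C	176.7	2.0
MET	H	8.26	0.60
MET	HA	4.41	0.48
MET	HB	2.03	0.35
MET	N	120.1	3.5
MET	CA	56.1	2.2
MET	CB	33.0	2.2
MET	C	176.3	2.1
PHE	H	8.36	0.72
PHE	HA	4.62	0.57
PHE	HB	3.00	0.37
PHE	N	120.4	4.2
PHE	CA	58.1	2.6
PHE	CB	39.9	2.1
PHE	C	175.5	2.0
PRO	HA	4.40	0.33
PRO	HB	2.07	0.35
PRO	N	136.6	4.5
PRO	CA	63.3	1.5
PRO	CB	31.8	1.2
PRO	C	176.7	1.5
SER	H	8.28	0.59
SER	HA	4.49	0.40
SER	HB	3.88	0.26
SER	N	116.3	3.5
SER	CA	58.7	2.1
SER	CB	63.8	1.5
SER	C	174.6	1.7
THR	H	8.24	0.61
THR	HA	4.47	0.48
THR	HB	4.16	0.34
THR	N	115.4	4.7
THR	CA	62.2	2.6
THR	CB	69.7	1.6
THR	C	174.5	1.7
TRP	H	8.28	0.78
TRP	HA	4.69	0.52
TRP	HB	3.19	0.35
TRP	N	121.7	4.1
TRP	CA	57.7	2.6
TRP	CB	30.0	2.0
TRP	C	176.1	2.0
TYR	H	8.30	0.73
TYR	HA	4.63	0.56
TYR	HB	2.92	0.39
TYR	N	120.5	4.3
TYR	CA	58.1	2.5
TYR	CB	39.3	2.2
TYR	C	175.4	2.0
VAL	H	8.27	0.67
VAL	HA	4.17	0.57
VAL	HB	2.05	0.32
VAL	N	121.1	4.6
VAL	CA	62.5	2.9
VAL	CB	32.7	1.8
VAL	C	175.7	1.9
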