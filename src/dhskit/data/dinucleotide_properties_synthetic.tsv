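dinucleotide	shift	slide	rise	twist	tilt	roll
AA	-0.03	-0.08	3.27	35.6	-1.4	0.7
AC	0.13	-0.58	3.36	32.2	-0.1	0.7
AG	0.09	-0.25	3.34	27.7	-1.7	4.5
AT	0.00	-0.59	3.31	31.5	0.0	1.1
CA	0.09	0.53	3.33	34.5	0.5	4.7
CC	0.05	-0.22	3.42	33.7	-0.1	3.6
CG	0.00	0.41	3.39	29.8	0.0	5.4
CT	-0.09	-0.25	3.34	27.7	1.7	4.5
GA	-0.28	0.09	3.37	36.9	-1.5	1.9
GC	0.00	-0.38	3.40	40.0	0.0	0.3
GG	-0.05	-0.22	3.42	33.7	0.1	3.6
GT	-0.13	-0.58	3.36	32.2	0.1	0.7
TA	0.00	0.05	3.42	36.0	0.0	3.3
TC	0.28	0.09	3.37	36.9	1.5	1.9
TG	-0.09	0.53	3.33	34.5	-0.5	4.7
TT	0.03	-0.08	3.27	35.6	1.4	0.7
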