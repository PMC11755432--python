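family	attribute	weight	n_active	n_passive	n_calibration
sk	O	-0.4891	33	31	33
sk	=	-0.1378	30	25	34
sk	P	2.5439	4	2	1
sk	(	-0.2469	34	33	35
sk	O	-0.4891	33	31	33
sk	c	-0.2147	28	30	30
sk	1	0.5435	30	32	32
sk	c	-0.2147	28	30	30
sk	c	-0.2147	28	30	30
sk	c	-0.2147	28	30	30
sk	(	-0.2469	34	33	35
sk	c	-0.2147	28	30	30
sk	(	-0.2469	34	33	35
sk	c	-0.2147	28	30	30
sk	1	0.5435	30	32	32
sk	(	-0.2469	34	33	35
sk	C	0.0241	34	33	35
sk	(	-0.2469	34	33	35
sk	S	0.7864	12	11	11
sk	C	0.0241	34	33	35
sk	(	-0.2469	34	33	35
sk	(	-0.2469	34	33	35
sk	O	-0.4891	33	31	33
sk	C	0.0241	34	33	35
sk	C	0.0241	34	33	35
sk	(	-0.2469	34	33	35
sk	N	0.7755	25	23	29
sk	C	0.0241	34	33	35
sk	(	-0.2469	34	33	35
sk	C	0.0241	34	33	35
sk	(	-0.2469	34	33	35
sk	C	0.0241	34	33	35
ssk	O...=	0.0016	29	24	30
ssk	P...=	8.2913	1	1	0
ssk	P...(	2.0343	4	2	1
ssk	O...(	0.2868	30	23	26
ssk	c...O	0.7112	7	8	8
ssk	c...1	0.2000	25	26	30
ssk	c...1	0.2000	25	26	30
ssk	c...c	0.0593	28	29	29
ssk	c...c	0.0593	28	29	29
ssk	c...(	0.0243	27	28	27
ssk	c...(	0.0243	27	28	27
ssk	c...(	0.0243	27	28	27
ssk	c...(	0.0243	27	28	27
ssk	c...1	0.2000	25	26	30
ssk	1...(	1.6836	19	19	11
ssk	C...(	0.0663	33	32	35
ssk	C...(	0.0663	33	32	35
ssk	S...(	1.1459	12	9	8
ssk	S...C	0.8502	5	5	8
ssk	C...(	0.0663	33	32	35
ssk	(...(	-0.5271	22	19	21
ssk	O...(	0.2868	30	23	26
ssk	O...C	0.1543	21	22	16
ssk	C...C	0.7926	19	16	18
ssk	C...(	0.0663	33	32	35
ssk	N...(	-0.7782	19	21	22
ssk	N...C	0.0455	9	13	8
ssk	C...(	0.0663	33	32	35
ssk	C...(	0.0663	33	32	35
ssk	C...(	0.0663	33	32	35
ssk	C...(	0.0663	33	32	35
fls	[xyx7]	-0.8997	6	1	6
fls	[xyyx0]	0.5900	29	29	24
fls	[xyzyx1]	0.0854	9	8	8
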