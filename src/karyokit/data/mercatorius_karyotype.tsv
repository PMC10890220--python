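# Hemidactylus mercatorius karyotype: 21 pairs, 2n = 42, FN = 54.
# RL and CI as published mean ± SD (percent); NOR on pair 14.
pair_id	rl_mean	rl_sd	ci_mean	ci_sd	class	nor
1	9.0	1.1	43.5	3.7	m	0
2	8.9	1.0	10.6	1.7	a	0
3	8.3	0.9	4.2	2.0	a	0
4	7.6	0.8	34.1	2.5	sm	0
5	7.0	0.7	15.6	3.0	st	0
6	6.1	0.7	3.3	1.1	a	0
7	6.0	0.4	5.2	2.1	a	0
8	6.0	0.5	4.8	3.0	a	0
9	5.5	0.6	6.3	2.9	a	0
10	4.9	0.6	2.8	1.2	a	0
11	4.1	0.5	15.8	3.5	st	0
12	3.9	0.4	4.8	2.8	a	0
13	3.4	0.4	9.3	3.7	a	0
14	3.3	0.5	7.4	4.2	a	1
15	2.7	0.3	6.5	3.0	a	0
16	2.6	0.7	10.2	1.9	a	0
17	2.6	0.6	3.2	2.1	a	0
18	2.5	0.4	42.8	4.2	m	0
19	2.1	0.5	44.4	2.7	m	0
20	1.9	0.5	42.9	3.8	m	0
21	1.8	0.4	45.3	4.0	m	0
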