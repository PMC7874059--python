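isolate	ST	pyrG	rpoB	groEL	recA	uvrC	carB	murC	pheS
qz279	7	2	9	2	1	2	10	4	1
qz280	7	2	9	2	1	2	10	4	1
qz504	8	1	1	1	1	3	7	1	1
qz546	8	1	1	1	1	3	7	1	1
qz547	8	1	1	1	1	3	7	1	1
qz549	8	1	1	1	1	3	7	1	1
qz534	9	1	3	1	1	1	1	1	2
qz544	9	1	3	1	1	1	1	1	2
qz545	9	1	3	1	1	1	1	1	2
qz540	10	3	2	1	1	1	1	3	1
qz541	10	3	2	1	1	1	1	3	1
qz547-2	12	1	3	1	1	1	7	1	2
qz594	12	1	3	1	1	1	7	1	2
qz569	13	2	1	6	1	1	5	1	5
qz695	13	2	1	6	1	1	5	1	5
qz770	13	2	1	6	1	1	5	1	5
qz733	14	3	2	4	1	6	1	3	1
qz768	14	3	2	4	1	6	1	3	1
qz771	14	3	2	4	1	6	1	3	1
cw18	17	1	3	1	1	1	1	2	2
cw19	17	1	3	1	1	1	1	2	2
cw21	17	1	3	1	1	1	1	2	2
cw22	17	1	3	1	1	1	1	2	2
cw23	19	2	6	1	1	1	5	1	3
cw32	19	2	6	1	1	1	5	1	3
cw33	19	2	6	1	1	1	5	1	3
cw34	19	2	6	1	1	1	5	1	3
JCM6124	1	7	1	4	1	6	11	1	3
CGMCC1.2138	2	6	1	7	1	3	9	1	5
JCM16943	3	2	8	2	5	4	9	6	3
CGMCC1.2141	4	5	5	2	1	5	13	1	3
qz274	5	1	3	1	1	1	3	1	2
qz275	6	2	1	6	1	1	8	1	5
qz769	15	1	3	4	1	6	1	1	2
cw17	16	1	3	1	1	1	4	1	1
cw20	18	2	6	1	1	7	5	1	3
cw25	20	2	7	5	3	9	2	1	1
cw26	21	2	4	5	4	8	2	1	1
cw27	22	2	4	2	6	1	12	5	3
cw28	23	4	1	1	1	3	6	1	1
cw29	24	2	4	1	3	10	2	1	1
cw31	25	1	1	1	1	3	1	1	1
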