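protein	n_segments	n_sticks	volume	beta	sk	sk+g	sk+g+e	sk+e	g	g+e
1FLP	7	6	simulated	0	1	1	1	1	4	17
1NG6	9	7	simulated	0	2	2	1	1	7	15
2XB5	13	10	simulated	0	11	2	9	47	91	NA
1BZ4	5	5	simulated	0	1	1	3	56	87	NA
3ACW	17	15	simulated	0	32	7	24	28	73	61
1A7D	6	4	simulated	0	12	2	17	19	46	94
3ODS	21	16	simulated	0	7	1	34	61	NA	NA
3HJL	20	20	simulated	0	1	1	1	1	4	16
1ICX	13	11	simulated	1	31	12	45	NA	NA	NA
1OZ9	13	12	simulated	1	2	2	3	4	72	NA
4OXW	8	7	simulated	1	6	1	2	2	18	77
1YD0	8	7	simulated	1	31	5	22	NA	NA	65
2Y4Z	8	8	simulated	1	NA	14	59	92	NA	83
4YOK	17	15	simulated	1	NA	37	NA	87	NA	NA
4R9A	14	10	simulated	1	NA	27	NA	NA	NA	NA
3FIN	7	7	experimental	1	1	2	2	5	5	24
4CHV	23	19	experimental	1	NA	NA	NA	NA	NA	NA
5I1M	19	12	experimental	0	NA	NA	NA	NA	NA	NA
6F36	13	7	experimental	0	2	1	3	19	2	63
6EM3	8	8	experimental	1	27	13	77	NA	51	NA
4UE4	6	5	experimental	0	1	1	3	14	11	56
5UZB	13	7	experimental	1	20	9	29	77	NA	NA
3C91	19	19	experimental	1	NA	51	87	NA	NA	NA
5O8O	24	22	experimental	1	NA	NA	NA	NA	NA	NA
5M50	9	8	experimental	1	41	31	55	82	NA	NA
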