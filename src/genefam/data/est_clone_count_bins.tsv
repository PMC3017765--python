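n_est_clones	n_genes
0	22
1	8
2	4
3	8
4	3
5	1
6	2
7	7
8	1
9	2
10	0
11	3
12	0
13	0
14	3
>15	5
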