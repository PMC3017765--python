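tissue	n_genes	n_est_clones
midgut	23	104
corpora allata	12	39
silk gland	12	34
ovary	12	25
brain	10	16
pheromone gland	10	15
wing	9	16
fat body	8	25
hemocyte	6	22
testis	5	8
compound eyes	4	10
maxillary galea	4	7
epidermis	3	3
Malpighian tubules	2	19
Verson's gland	2	9
prothoracic gland	2	2
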