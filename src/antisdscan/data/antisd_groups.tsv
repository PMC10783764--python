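group	first	last	length	antisd	sd
1	-2	6	9	CCUCCUUUC	GAAAGGAGG
2	-1	5	7	CUCCUUU	AAAGGAG
3	-2	5	8	CCUCCUUU	AAAGGAGG
4	-3	5	9	ACCUCCUUU	AAAGGAGGU
5	-5	5	11	UCACCUCCUUU	AAAGGAGGUGA
6	-5	4	10	UCACCUCCUU	AAGGAGGUGA
7	-4	4	9	CACCUCCUU	AAGGAGGUG
8	-2	4	7	CCUCCUU	AAGGAGG
9	-3	4	8	ACCUCCUU	AAGGAGGU
10	-3	3	7	ACCUCCU	AGGAGGU
11	-4	3	8	CACCUCCU	AGGAGGUG
12	-5	3	9	UCACCUCCU	AGGAGGUGA
13	-6	3	10	AUCACCUCCU	AGGAGGUGAU
14	-5	2	8	UCACCUCC	GGAGGUGA
15	-6	1	8	AUCACCUC	GAGGUGAU
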