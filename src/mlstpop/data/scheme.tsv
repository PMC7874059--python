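name	fragment_length	primer_f	primer_r
pyrG	598	GTTACTGGCGATGGTTTAG	AGACATTTCTGCCTTTGG
rpoB	608	GCATTTTGGAACGACTGT	TGGGTTTTCGGGAGAT
groEL	656	TGAAGCCTTGCCAACA	CACTCATCAGTAGCAGCGT
recA	550	ATCCCAAGGGGCGTAT	GCAACTTTGAATGGTGGAG
uvrC	560	CTTGTTTCCGTGATGTTCC	CCTTCATTGCCCCAGTC
carB	833	TAAAGCCTTGATGGAACG	ATTGCGACCGATAGCC
murC	619	TCCATTAGAGGCAGCAGG	GGTTTCAAAGAACGCAAGT
pheS	665	AACAGGTTTGCTGAAGGG	GGGAAATAAGAAGGTCGC
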