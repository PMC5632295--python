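#name	pool	fwd_primers	rev_primers	min_len	len_lo	len_hi
16S	16S	CGCCTGTTTATCAAAAACAT	CCGGTCTGAACTCAGATCACGT	200	500	600
mini-16S	mini-16S	AYAAGACGAGAAGACCC	GATTGCGCTGTTATTCC	200	250	250
COI	COI	ATTCAACCAATCATAAAGATATTGG;TTCTCAACCAACCACAAAGACATTGG;TTCTCAACCAACCACAARGAYATYGG;TTCTCAACCAACCAIAAIGAIATIGG	TAAACTTCTGGATGTCCAAAAAATCA;TAGACTTCTGGGTGGCCRAARAAYCA;TAGACTTCTGGGTGGCCAAAGAATCA;TAGACTTCTGGGTGICCIAAIAAICA	200	648	648
mini-COI	COI	GGWACWGGWTGAACWGTWTAYCCYCC	TAIACYTCIGGRTGICCRAARAAYCA	200	313	313
cyt b	cyt b	CCATCCAACATCTCAGCATGATGAAA	GGCAAATAGGAARTATCATTC	200	743	743
mini-cyt b	cyt b	CCATCCAACATCTCAGCATGATGAAA	CCCTCAGAATGATATTTGTCCTCA	200	357	357
matK	matK	ACCCAGTCCATCTGGAAATCTTGGTTC	CGTACAGTACTTTTGTGTTTACGAG	200	656	889
rbcL	rbcL	ATGTCACCACAAACAGAGACTAAAGC	GTAAAATCAAGTCCACCRCG	200	654	654
mini-rbcL	mini-rbcL	GTTGGATTCAAAGCTGGTGTTA	CVGTCCAMACAGTWGTCCATGT	140	140	140
trnL-UAA	trnL-UAA	CGAAATCGGTAGACGCTACG	GGGGATAGAGGGACTTGAAC	200	767	767
trnL-P6	trnL-P6	GGGCAATCCTGAGCCAA	CCATTGAGTCTCTGCACCTATC	10	10	143
ITS2	ITS2	ATGCGATACTTGGTGTGAAT	GACGCTTCTCCAGACTACAAT	100	160	320
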