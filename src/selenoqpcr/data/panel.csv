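gene,protein,family,forward_primer,reverse_primer
Th,Th,marker,CAGCTGGAGGATGTGTCTCA,GGCATGACGGATGTACTGTG
Dio1,Dio1,DIO,CTGCCTGAGAGGCTCTACGT,ACTTCATCTGGGAACACAGG
Dio2,Dio2,DIO,GATCCTGCCAGTCTTTT,ATTGGGAGCATCTTCAC
Dio3,Dio3,DIO,GTCCTGGACACTATGGCCAA,TCTTTGGAGCATTTGCACGT
Gpx1,Gpx1,GPX,TGGACTGGTGGTGCTCG,CGTCACTGGGTGTTGGC
Gpx2,Gpx2,GPX,GGGCTGTGCTGATTGAGA,CGGACATACTTGAGGCTGTT
Gpx3,Gpx3,GPX,GGCTTCCCTTCCAACC,AATTTCTGCTCTTTCTCCC
Gpx4,Gpx4,GPX,ACGATGCCCACCCACT,CCACGCAGCCGTTCTT
Txnrd1,TrxR1,TrxR,CCTATGTCGCCTTGGAATGTGC,ATGGTCTCCTCGCTGTTTGTGG
Txnrd2,TrxR2,TrxR,GGCTCAGCGGCTCTTT,CGCCACCGTGAACTCT
Txnrd3,TGR,TrxR,CAAGTTGATGACGGG,TTGGCACAAGAGAGG
Sep15,Sep15,ER,CTGGCGACTGCGTTTC,TCCTGACAGCACCCTCT
Selm,SelM,ER,TCGCCTAAAGGAGGTGAAG,CATTTGGCTGAGTGGGATT
Selh,SelH,Rdx,GCCTATGGAGACGGTGGA,GCGGTTTGGACGGGTT
Selt,SelT,Rdx,TTATCTCCCTCAACCAA,CTCAGGAAGAAAACCAT
Sepw1,SelW,Rdx,TAAGCCCAAGTACCTCCA,CCACATAGCCATCACCTC
Selv,SelV,Rdx,CAGGAGGAAGCATGCAAGA,TGGTTTGGCAGCATTTCAG
Selk,SelK,KS,AAAGAAGAGGCTACGGG,TTACCTTCCTCATCCACC
Sels,SelS,KS,CTTTGCGAGGAGGTGGTTAT,CCTTGCTAATGTCAGAGCGA
Seli,SelI,other,TCCGTGTTTGCTCTTCA,CGTGCTGCTCATTTGG
Sepp1,SelP,other,GGCCGTCTTGTGTATCACCT,TGGTGTTTGTGGTGGCTATG
Selo,SelO,other,CCAGCGTGGGACGAGAT,CTGCCATTCAGCAACCAT
Msrb1,MsrB1,other,CTTCGGAGGCGAGGTT,TGGGTGGATGGTTTCAG
Sepn1,SelN,other,GACTTCCCCTTCTGGTT,TGTTGCTGGTCTCACTG
Sephs2,SPS2,other,GTGCCGTGGTAGGAGATGTG,GCAGTCCTGTTTAGAGTAGCCATA
Actb,beta-actin,reference,CTGTCCCTGTATGCCTCTG,ATGTCACGCACGATTTCC
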