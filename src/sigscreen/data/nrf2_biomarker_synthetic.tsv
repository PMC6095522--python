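probe_id	gene_id	avg_fold_change
1417019_at	Nqo1	1.57
1417024_at	Gclc	1.53
1417060_at	Gclm	1.6
1417076_at	Gsta1	5.07
1417084_at	Gsta2	2.42
1417109_at	Gstm1	2.2
1417147_at	Gstm2	1.54
1417167_at	Gstm3	3.87
1417180_at	Gstm4	5.9
1417207_at	Gstp1	2.31
1417246_at	Txnrd1	2.17
1417271_at	Gpx2	2.77
1417281_at	Ephx1	2.09
1417285_at	Cbr1	4.2
1417301_at	Cbr3	1.87
1417339_at	Abcc3	6.98
1417359_at	Abcc4	2.14
1417380_at	Ces1g	3.99
1417406_at	Cyp2a5	2.87
1417423_at	Akr1b8	2.4
1417461_at	Prdx1	13.79
1417465_at	Sqstm1	1.51
1417502_at	Fth1	2.11
1417513_at	Ftl1	3.78
1417540_at	Me1	4.05
1417548_at	G6pdx	2.69
1417563_at	Pgd	1.87
1417600_at	Idh1	2.45
1417612_at	Srxn1	3.64
1417633_at	Mgst3	2.11
1417639_at	Ugdh	2.87
1417667_at	Cat	1.8
1417680_at	Slc7a11	3.04
1417693_at	Cyp4v3	-1.54
1417709_at	C8a	-1.84
1417732_at	Nudt7	-2.29
1417735_at	Car3	-2.44
1417766_at	Tsc22d1	-2.09
1417795_at	Cyp7b1	-2.71
1417834_at	Hsd3b5	-3.03
1417870_at	Slco1a1	-2.11
1417894_at	Elovl3	-1.67
1417910_at	Cyp4a12a	-4.33
1417930_at	Serpina1e	-1.89
1417966_at	Mup3	-12.32
1417973_at	Selenbp2	-1.91
1417978_at	Sult1e1	-2.32
1418005_at	Acot3	-2.18
1418029_at	Cbr3	4.41
1418066_at	Gstm4	1.73
1418096_at	Sqstm1	1.62
1418122_at	Gsta1	1.63
1418138_at	Cbr1	7.98
1418176_at	Gstm2	2.87
1418192_at	Pgd	2.91
1418226_at	Akr1b8	2.74
1418246_at	Ugdh	2.42
1418272_at	Ces1g	2.37
1418309_at	Gsta2	3.31
1418315_at	Idh1	2.18
1418332_at	Mgst3	1.52
1418348_at	Abcc4	1.82
1418367_at	Txnrd1	5.67
1418388_at	Cat	2.15
1418422_at	Ephx1	2.52
1418428_at	Gstp1	2.38
1418465_at	G6pdx	5.13
1418496_at	Tsc22d1	-1.55
1418506_at	Acot3	-1.82
1418540_at	Mup3	-2.06
1418556_at	C8a	-5.25
1418582_at	Cyp4v3	-1.87
1418608_at	Hsd3b5	-6.72
1418638_at	Selenbp2	-3.71
1418668_at	Car3	-6.32
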