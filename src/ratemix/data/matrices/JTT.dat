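# JTT amino-acid exchangeability matrix
# source: Jones, Taylor & Thornton (1992)
# order: ARNDCQEGHILKMFPSTWYV; lower triangle then frequencies
58
54 45
81 16 528
56 113 34 10
57 310 86 49 9
105 29 58 767 5 323
179 137 81 130 59 26 119
27 328 391 112 69 597 26 23
36 22 47 11 17 9 12 6 16
30 38 12 7 23 72 9 6 56 229
35 646 263 26 7 292 181 27 45 21 14
54 44 30 15 31 43 18 14 33 479 388 65
15 5 10 4 78 4 5 5 40 89 248 4 43
194 74 15 15 14 164 18 24 115 10 102 21 16 17
378 101 503 59 223 53 30 201 73 40 59 47 29 92 285
475 64 232 38 42 51 32 33 46 245 25 103 226 12 118 477
9 126 8 4 115 18 10 55 8 9 52 10 24 53 6 35 12
11 20 70 46 209 24 7 8 573 32 24 8 18 536 10 63 21 71
298 17 16 31 62 20 45 47 11 961 180 14 323 62 23 38 112 25 16

0.0767479232521 0.0516909483091 0.042644957355 0.0515439484561 0.019802980197 0.040751959248 0.0618299381701 0.0731519268481 0.022943977056 0.0537609462391 0.0919039080961 0.0586759413241 0.023825976174 0.040125959874 0.0509009490991 0.0687649312351 0.0585649414351 0.014260985739 0.032101967898 0.0660049339951
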