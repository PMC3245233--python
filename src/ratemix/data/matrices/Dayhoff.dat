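# Dayhoff amino-acid exchangeability matrix
# source: Dayhoff, Schwartz & Orcutt (1978) PAM model
# order: ARNDCQEGHILKMFPSTWYV; lower triangle then frequencies
27
98 32
120 0 905
36 23 0 0
89 246 103 134 0
198 1 148 1153 0 716
240 9 139 125 11 28 81
23 240 535 86 28 606 43 10
65 64 77 24 44 18 61 0 7
41 15 34 0 0 73 11 7 44 257
26 464 318 71 0 153 83 27 26 46 18
72 90 1 0 0 114 30 17 0 336 527 243
18 14 14 0 0 0 0 15 48 196 157 0 92
250 103 42 13 19 153 51 34 94 12 32 33 17 11
409 154 495 95 161 56 79 234 35 24 17 96 62 46 245
371 26 229 66 16 53 34 30 22 192 33 136 104 13 78 550
0 201 23 0 0 0 0 0 27 0 46 0 0 76 0 75 0
24 8 95 0 96 0 22 0 127 37 28 13 0 698 0 34 42 61
208 24 15 18 49 35 37 54 44 889 175 10 258 12 48 30 157 0 28

0.0871269128731 0.040903959096 0.040431959568 0.046871953128 0.033473966526 0.038254961745 0.04952995047 0.0886119113881 0.033617966382 0.036885963114 0.0853569146431 0.0804819195181 0.014752985247 0.039771960228 0.0506799493201 0.0695769304231 0.0585419414581 0.010493989506 0.029915970084 0.0647179352821
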