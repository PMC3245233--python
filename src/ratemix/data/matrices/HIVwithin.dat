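# HIVwithin amino-acid exchangeability matrix
# source: Nickle et al. (2007) HIV within-host
# order: ARNDCQEGHILKMFPSTWYV; lower triangle then frequencies
0.0744808
0.617509 0.16024
4.43521 0.0674539 29.4087
0.167653 2.86364 0.0604932 0.005
0.005 10.6746 0.342068 0.005 0.005
5.56325 0.0251632 0.201526 12.1233 0.005 3.20656
1.8685 13.4379 0.0604932 10.3969 0.0489798 0.0604932 14.7801
0.005 6.84405 8.59876 2.31779 0.005 18.5465 0.005 0.005
0.005 1.34069 0.987028 0.145124 0.005 0.0342252 0.0390512 0.005 0.005
0.16024 0.586757 0.005 0.005 0.005 2.89048 0.129839 0.0489798 1.76382 9.10246
0.592784 39.8897 10.6655 0.894313 0.005 13.0705 23.9626 0.279425 0.22406 0.817481 0.005
0.005 3.28652 0.201526 0.005 0.005 0.005 0.005 0.0489798 0.005 17.3064 11.3839 4.09564
0.597923 0.005 0.005 0.005 0.362959 0.005 0.005 0.005 0.005 1.48288 7.48781 0.005 0.005
1.00981 0.404723 0.344848 0.005 0.005 3.04502 0.005 0.005 13.9444 0.005 9.83095 0.111928 0.005 0.0342252
8.5942 8.35024 14.5699 0.427881 1.12195 0.16024 0.005 6.27966 0.725157 0.740091 6.14396 0.005 0.392575 4.27939 14.249
24.1422 0.928203 4.54206 0.630395 0.005 0.203091 0.458743 0.0489798 0.95956 9.36345 0.005 4.04802 7.41313 0.114512 4.33701 6.34079
0.005 5.96564 0.005 0.005 5.49894 0.0443298 0.005 2.8258 0.005 0.005 1.37031 0.005 0.005 0.005 0.005 1.10156 0.005
0.005 0.005 5.06475 2.28154 8.34835 0.005 0.005 0.005 47.4889 0.114512 0.005 0.005 0.579198 4.12728 0.005 0.933142 0.490608 0.005
24.8094 0.279425 0.0744808 2.91786 0.005 0.005 2.19952 2.79622 0.827479 24.8231 2.95344 0.128065 14.7683 2.28 0.005 0.862637 0.005 0.005 1.35482

0.0377493962251 0.0573209942679 0.0891128910887 0.0342033965797 0.024010497599 0.0437823956218 0.0618605938139 0.083849591615 0.0156075984392 0.0983640901636 0.0577866942213 0.0641681935832 0.0158418984158 0.0422740957726 0.045860095414 0.0550845944915 0.0813773918623 0.0195969980403 0.0205846979415 0.0515638948436
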