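# HIVbetween amino-acid exchangeability matrix
# source: Nickle et al. (2007) HIV between-host
# order: ARNDCQEGHILKMFPSTWYV; lower triangle then frequencies
0.307507
0.005 0.295543
1.45504 0.005 17.6612
0.123758 0.351721 0.0860642 0.005
0.0551128 3.4215 0.672052 0.005 0.005
1.48135 0.0749218 0.0792633 10.5872 0.005 2.5602
2.13536 3.65345 0.323401 2.83806 0.897871 0.0619137 3.92775
0.0847613 9.04044 7.64585 1.9169 0.240073 7.05545 0.11974 0.005
0.005 0.677289 0.680565 0.0176792 0.005 0.005 0.00609079 0.005 0.103111
0.215256 0.701427 0.005 0.00876048 0.129777 1.49456 0.005 0.005 1.74171 5.95879
0.005 20.45 7.90443 0.005 0.005 6.54737 4.61482 0.521705 0.005 0.322319 0.0814995
0.0186643 2.51394 0.005 0.005 0.005 0.303676 0.175789 0.005 0.005 11.2065 5.31961 1.28246
0.0141269 0.005 0.005 0.005 9.29815 0.005 0.005 0.291561 0.145558 3.39836 8.52484 0.0342658 0.188025
2.12217 1.28355 0.00739578 0.0342658 0.005 4.47211 0.0120226 0.005 2.45318 0.0410593 2.07757 0.0313862 0.005 0.005
2.46633 3.4791 13.1447 0.52823 4.69314 0.116311 0.005 4.38041 0.382747 1.21803 0.927656 0.504111 0.005 0.956472 5.37762
15.9183 2.86868 6.88667 0.274724 0.739969 0.243589 0.289774 0.369615 0.711594 8.61217 0.0437673 4.67142 4.94026 0.0141269 2.01417 8.93107
0.005 0.991338 0.005 0.005 2.63277 0.026656 0.005 1.21674 0.0695179 0.005 0.748843 0.005 0.089078 0.829343 0.0444506 0.0248728 0.005
0.005 0.00991826 1.76417 0.674653 7.57932 0.113033 0.0792633 0.005 18.6943 0.148168 0.111986 0.005 0.005 15.34 0.0304381 0.648024 0.105652 1.28022
7.61428 0.0812454 0.026656 1.04793 0.420027 0.0209153 1.02847 0.953155 0.005 17.7389 1.41036 0.265829 6.8532 0.723274 0.005 0.0749218 0.709226 0.005 0.0410593

0.0604902220605 0.066039665066 0.0441278150441 0.0421090480421 0.0200758990201 0.0536064880536 0.0715674470716 0.0723082390723 0.0222939430223 0.0697306290697 0.0988511220989 0.056968211057 0.0197683180198 0.0288094470288 0.046025282046 0.0506043300506 0.0536368130536 0.033011601033 0.0283502430284 0.0616252370616
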