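# Amino-acid physicochemical properties.
# chemical composition, polarity, volume: Grantham (1974);
# isoelectric point: standard free amino-acid pI values;
# hydropathy: Kyte & Doolittle (1982).
residue,chemical composition,polarity,volume,isoelectric point,hydropathy
A,0.0,8.1,31.0,6.0,1.8
R,0.65,10.5,124.0,10.76,-4.5
N,1.33,11.6,56.0,5.41,-3.5
D,1.38,13.0,54.0,2.77,-3.5
C,2.75,5.5,55.0,5.07,2.5
Q,0.89,10.5,85.0,5.65,-3.5
E,0.92,12.3,83.0,3.22,-3.5
G,0.74,9.0,3.0,5.97,-0.4
H,0.58,10.4,96.0,7.59,-3.2
I,0.0,5.2,111.0,6.02,4.5
L,0.0,4.9,111.0,5.98,3.8
K,0.33,11.3,119.0,9.74,-3.9
M,0.0,5.7,105.0,5.74,1.9
F,0.0,5.2,132.0,5.48,2.8
P,0.39,8.0,32.5,6.3,-1.6
S,1.42,9.2,32.0,5.68,-0.8
T,0.71,8.6,61.0,5.6,-0.7
W,0.13,5.4,170.0,5.89,-0.9
Y,0.2,6.2,136.0,5.66,-1.3
V,0.0,5.9,84.0,5.96,4.2
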