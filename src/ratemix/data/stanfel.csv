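# Stanfel (1996) classification of the 20 amino acids.
group,residues
I,AGPST
II,CILMV
III,DENQ
IV,HKR
V,FWY
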