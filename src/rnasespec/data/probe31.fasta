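>probe31 synthetic 31-nt specificity probe; all 16 dinucleotides + AAA/CCC/GGG/UUU runs; 5'-OH/3'-OH
GCAUCAGAAAUACACCCGUAGGGCUUUGAGA
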