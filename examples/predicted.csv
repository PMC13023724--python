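item_id,kind,multiplicity,region,c_shift,h_shift
C1H1,CH,tertiary,aliphatic,59.49,4.05
C5H5,CH,tertiary,aliphatic,59.74,3.20
C4H4,CH,tertiary,aliphatic,33.02,2.10
C8H8,CH,tertiary,aliphatic,65.31,3.41
C2,C,quaternary,carbonyl,171.2,
C3,C,quaternary,carbonyl,166.8,
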