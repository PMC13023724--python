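peak_id,multiplicity,region,c_shift,h_shift
a,tertiary,aliphatic,65.0,3.50
b,tertiary,aliphatic,59.9,3.30
c,tertiary,aliphatic,59.3,4.10
d,tertiary,aliphatic,33.5,2.00
q1,quaternary,carbonyl,171.9,
q2,quaternary,carbonyl,167.1,
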