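4
neutral post-insertion core, X trans to the Pd-bound alkyl carbon
Pd    0.000000    0.000000    0.000000
C     2.000000    0.000000    0.000000
Cl   -2.400000    0.000000    0.000000
P     0.000000    2.300000    0.000000
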