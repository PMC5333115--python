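run,A,B,C,cr,op
1,1,1,1,89.96,93.56
2,1,2,2,93.82,92.60
3,1,3,3,96.32,91.41
4,2,1,2,99.80,91.59
5,2,2,3,100.00,89.23
6,2,3,1,99.37,88.92
7,3,1,3,100.00,90.76
8,3,2,1,97.11,89.04
9,3,3,2,100.00,86.72
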