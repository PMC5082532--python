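code,atom,ppm
A,HN,8.24
A,HA,4.32
A,HB,1.39
D,HN,8.34
D,HA,4.64
D,HB,2.72
E,HN,8.42
E,HA,4.35
E,HB,2.01
E,HG,2.31
I,HN,8.00
I,HA,4.17
I,HB,1.87
I,HG,1.16
K,HN,8.29
K,HA,4.32
K,HB,1.84
K,HG,1.44
L,HN,8.16
L,HA,4.34
L,HB,1.62
L,HG,1.59
Q,HN,8.32
Q,HA,4.34
Q,HB,2.08
Q,HG,2.36
R,HN,8.23
R,HA,4.34
R,HB,1.82
R,HG,1.63
S,HN,8.31
S,HA,4.47
S,HB,3.87
V,HN,8.03
V,HA,4.12
V,HB,2.08
V,HG,0.94
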