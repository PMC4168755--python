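# Random-coil 13C chemical shifts (ppm), Calpha and Cbeta, reduced cysteine.
# Reference set name: wishart1995 (values from the standard random-coil
# compilation used for secondary-shift indexing).
aa	CA	CB
A	52.5	19.1
C	58.2	28.0
D	54.2	41.1
E	56.6	29.9
F	57.7	39.6
G	45.1
H	55.0	29.0
I	61.1	38.8
K	56.2	33.1
L	55.1	42.4
M	55.4	32.9
N	53.1	38.9
P	63.3	31.7
Q	55.7	29.4
R	56.0	30.9
S	58.3	63.8
T	61.8	69.8
V	62.2	32.9
W	57.5	29.6
Y	57.9	38.8
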