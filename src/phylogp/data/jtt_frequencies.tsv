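# JTT equilibrium amino-acid frequencies (PAML order).
# Source: Jones, Taylor & Thornton (1992), values as distributed with PAML
# (jones.dat) and the R package phangorn.
aa	freq
A	0.07674792325
R	0.05169094831
N	0.04264495736
D	0.05154394846
C	0.01980298020
Q	0.04075195925
E	0.06182993817
G	0.07315192685
H	0.02294397706
I	0.05376094624
L	0.09190390810
K	0.05867594132
M	0.02382597617
F	0.04012595987
P	0.05090094910
S	0.06876493124
T	0.05856494144
W	0.01426098574
Y	0.03210196790
V	0.06600493400
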