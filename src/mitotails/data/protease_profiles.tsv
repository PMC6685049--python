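# M13.001
residue	P4	P3	P2	P1	P1'	P2'	P3'	P4'
A	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
C	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
D	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
E	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
F	0.050000	0.050000	0.050000	0.050000	0.250000	0.050000	0.050000	0.050000
G	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
H	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
I	0.050000	0.050000	0.050000	0.050000	0.150000	0.050000	0.050000	0.050000
K	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
L	0.050000	0.050000	0.050000	0.050000	0.250000	0.050000	0.050000	0.050000
M	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
N	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
P	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
Q	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
R	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
S	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
T	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
V	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
W	0.050000	0.050000	0.050000	0.050000	0.012500	0.050000	0.050000	0.050000
Y	0.050000	0.050000	0.050000	0.050000	0.150000	0.050000	0.050000	0.050000
# M16.003
residue	P4	P3	P2	P1	P1'	P2'	P3'	P4'
A	0.050000	0.050000	0.020000	0.050000	0.300000	0.050000	0.050000	0.050000
C	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
D	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
E	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
F	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
G	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
H	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
I	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
K	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
L	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
M	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
N	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
P	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
Q	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
R	0.050000	0.050000	0.620000	0.050000	0.025000	0.050000	0.050000	0.050000
S	0.050000	0.050000	0.020000	0.050000	0.250000	0.050000	0.050000	0.050000
T	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
V	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
W	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
Y	0.050000	0.050000	0.020000	0.050000	0.025000	0.050000	0.050000	0.050000
# S1C.002
residue	P4	P3	P2	P1	P1'	P2'	P3'	P4'
A	0.050000	0.050000	0.050000	0.110000	0.050000	0.050000	0.050000	0.050000
C	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
D	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
E	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
F	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
G	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
H	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
I	0.050000	0.050000	0.050000	0.250000	0.050000	0.050000	0.050000	0.050000
K	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
L	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
M	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
N	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
P	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
Q	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
R	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
S	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
T	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
V	0.050000	0.050000	0.050000	0.300000	0.050000	0.050000	0.050000	0.050000
W	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
Y	0.050000	0.050000	0.050000	0.020000	0.050000	0.050000	0.050000	0.050000
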