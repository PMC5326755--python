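# 14-segment uppercase font: letter followed by 14 binary flags.
# Segment order: top, upper-right, lower-right, bottom, lower-left,
# upper-left, mid-left, mid-right, diag-upper-left, vert-top,
# diag-upper-right, diag-lower-left, vert-bottom, diag-lower-right
A	1	1	1	0	1	1	1	1	0	0	0	0	0	0
B	1	1	1	1	0	0	0	1	0	1	0	0	1	0
C	1	0	0	1	1	1	0	0	1	0	1	1	0	0
D	1	1	1	1	0	0	0	0	1	1	0	0	1	0
E	1	0	0	1	1	1	1	0	1	0	1	0	0	0
F	1	0	0	0	1	1	1	0	1	0	1	1	0	0
G	1	0	1	1	1	1	0	1	1	0	0	0	0	0
H	0	1	1	0	1	1	1	1	1	0	0	0	0	0
I	1	0	0	1	0	0	0	0	1	1	1	1	1	0
J	0	1	1	1	1	0	0	0	1	0	1	1	0	0
K	0	0	0	0	1	1	1	0	1	0	1	1	0	1
L	0	0	0	1	1	1	0	0	1	0	1	1	0	1
M	0	1	1	0	1	1	0	0	1	0	1	1	0	0
N	0	1	1	0	1	1	0	0	1	0	1	0	0	1
O	1	1	1	1	1	1	0	0	1	0	0	0	0	0
P	1	1	0	0	1	1	1	1	1	0	0	0	0	0
Q	1	1	1	1	1	1	0	0	0	0	0	0	0	1
R	1	1	0	0	1	1	1	1	0	0	0	0	0	1
S	1	0	1	1	0	1	1	1	1	0	0	0	0	0
T	1	0	0	0	0	0	0	0	1	1	1	1	1	1
U	0	1	1	1	1	1	0	0	1	0	1	0	0	0
V	0	0	0	0	1	1	0	0	1	1	1	1	0	1
W	0	1	1	0	1	1	0	0	1	0	0	1	0	1
X	0	0	0	0	0	0	1	0	1	1	1	1	1	1
Y	0	0	0	0	0	0	0	1	1	1	1	1	1	1
Z	1	0	0	1	0	0	0	0	1	1	1	1	0	1
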