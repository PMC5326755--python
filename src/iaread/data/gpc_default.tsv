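# Default grapheme-phoneme correspondence rules for the synthetic alphabet.
# One rule per line: grapheme <TAB> phoneme <TAB> position-class.
# One-to-one letter rules cover the whole alphabet; the multi-letter rules
# below them exercise longest-match precedence.
A	a	any
B	b	any
C	c	any
D	d	any
E	e	any
F	f	any
G	g	any
H	h	any
I	i	any
J	j	any
K	k	any
L	l	any
M	m	any
N	n	any
O	o	any
P	p	any
Q	q	any
R	r	any
S	s	any
T	t	any
U	u	any
V	v	any
W	w	any
X	x	any
Y	y	any
Z	z	any
CH	C	any
TH	T	any
CK	k	final
EE	E	any
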