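# Synthetic 5-gene toy network.  Topology chosen so that an exhaustive
# search over the {AND_HI, OR_HI} operator pair yields a landscape whose
# attractors are exactly the two constraint states 10110 (22) and
# 11101 (29) plus one surplus attractor 01010 (10).
!genes: A B C D E
source	target	sign
B	C	activate
E	C	repress
D	A	repress
B	A	repress
A	B	repress
A	D	activate
E	D	repress
C	E	activate
B	E	repress
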