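# Reprogramming network: mouse embryonic fibroblast (MEF) to induced
# pluripotent stem cell (iPSC).  13 transcription factors plus the
# medium component LIF; 38 signed interactions from the published
# curated interaction table.
!genes: LIF Stat3 Klf4 Klf2 Esrrb Tcf3 MEKERK Gbx2 Sox2 Oct4 Tbx3 Tfcp2l1 Sall4 Nanog
!media: LIF
source	target	sign
LIF	Stat3	activate
Klf4	Klf2	activate
Esrrb	Klf2	activate
Tcf3	Klf2	repress
LIF	MEKERK	activate
MEKERK	Tcf3	repress
Klf4	Tcf3	activate
Stat3	Gbx2	activate
Sox2	Gbx2	activate
Oct4	Gbx2	repress
Stat3	Klf4	activate
Klf2	Klf4	activate
Gbx2	Klf4	activate
Klf4	Tbx3	activate
Tcf3	Tbx3	repress
Oct4	Tbx3	repress
Esrrb	Tbx3	activate
Tfcp2l1	Sall4	activate
Sox2	Sall4	activate
Tfcp2l1	Esrrb	activate
Nanog	Esrrb	activate
Sall4	Esrrb	activate
Tcf3	Esrrb	repress
Sall4	Oct4	activate
Tcf3	Oct4	activate
Stat3	Tfcp2l1	activate
Esrrb	Tfcp2l1	activate
Tcf3	Tfcp2l1	repress
Oct4	Tfcp2l1	activate
Oct4	Nanog	activate
Sall4	Nanog	activate
Sox2	Nanog	activate
MEKERK	Nanog	repress
Tbx3	Sox2	activate
Nanog	Sox2	activate
Sall4	Sox2	activate
Tcf3	Sox2	activate
MEKERK	Sox2	repress
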