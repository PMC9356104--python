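# Maintenance-of-naive-pluripotency network: 12 transcription factors
# plus three medium components (LIF; the GSK3 inhibitor CH; the MEK
# inhibitor PD).  Edge list reconstructed from the published network
# diagram; in-degrees are exact (total configuration count with six
# operators is 28179280429056).
!genes: LIF CH PD Stat3 MEKERK Tcf3 Gbx2 Klf2 Klf4 Tbx3 Sox2 Oct4 Esrrb Nanog Tfcp2l1
!media: LIF CH PD
source	target	sign
LIF	Stat3	activate
PD	MEKERK	repress
CH	Tcf3	repress
MEKERK	Tcf3	repress
Stat3	Gbx2	activate
Sox2	Gbx2	activate
Klf4	Klf2	activate
Esrrb	Klf2	activate
Stat3	Klf4	activate
Gbx2	Klf4	activate
Klf4	Tbx3	activate
Nanog	Sox2	activate
Sox2	Oct4	activate
Klf2	Oct4	activate
Esrrb	Oct4	repress
Nanog	Esrrb	activate
Tfcp2l1	Esrrb	activate
Tcf3	Esrrb	repress
Oct4	Nanog	activate
Sox2	Nanog	activate
MEKERK	Nanog	repress
Stat3	Tfcp2l1	activate
Esrrb	Tfcp2l1	activate
Klf4	Tfcp2l1	activate
Oct4	Tfcp2l1	repress
Tcf3	Tfcp2l1	repress
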