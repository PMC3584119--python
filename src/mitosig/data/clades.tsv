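taxon	clade
T_herculeana	A
T_processionea	A
T_solitaria	A
T_pityocampa	B
T_pityocampa_ENA	B
T_wilkinsoni	B
T_ispartaensis	C
T_libanotica	C
T_bonjeani	C
T_pinivora	C
O_lunifer	outgroup
H_cunea	outgroup
L_dispar	outgroup
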