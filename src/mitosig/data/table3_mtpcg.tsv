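taxon	O_lunifer	T_solitaria	T_herculeana	T_processionea	T_wilkinsoni	T_pityocampa_ENA	T_pityocampa	T_ispartaensis	T_libanotica	T_bonjeani	T_pinivora
O_lunifer
T_solitaria	0.158
T_herculeana	0.166	0.116
T_processionea	0.169	0.124	0.125
T_wilkinsoni	0.173	0.134	0.144	0.145
T_pityocampa_ENA	0.170	0.138	0.141	0.146	0.082
T_pityocampa	0.168	0.138	0.142	0.142	0.083	0.074
T_ispartaensis	0.175	0.138	0.138	0.144	0.117	0.114	0.122
T_libanotica	0.170	0.134	0.135	0.140	0.113	0.112	0.116	0.042
T_bonjeani	0.163	0.127	0.133	0.132	0.109	0.110	0.112	0.066	0.065
T_pinivora	0.164	0.129	0.132	0.135	0.111	0.111	0.112	0.064	0.062	0.047
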