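taxon	O_lunifer	T_solitaria	T_herculeana	T_processionea	T_wilkinsoni	T_pityocampa_ENA	T_pityocampa	T_ispartaensis	T_libanotica	T_bonjeani	T_pinivora
O_lunifer
T_solitaria	0.115
T_herculeana	0.114	0.039
T_processionea	0.113	0.031	0.033
T_wilkinsoni	0.113	0.059	0.065	0.061
T_pityocampa_ENA	0.112	0.057	0.063	0.059	0.005
T_pityocampa	0.112	0.056	0.062	0.058	0.006	0.005
T_ispartaensis	0.116	0.061	0.067	0.060	0.031	0.030	0.029
T_libanotica	0.115	0.061	0.066	0.060	0.032	0.031	0.029	0.002
T_bonjeani	0.117	0.060	0.064	0.059	0.032	0.031	0.029	0.005	0.004
T_pinivora	0.116	0.060	0.064	0.059	0.031	0.030	0.028	0.005	0.004	0.003
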