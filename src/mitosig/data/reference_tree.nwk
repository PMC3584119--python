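(H_cunea:0.30,(L_dispar:0.28,(O_lunifer:0.17,(((T_herculeana:0.06,T_processionea:0.06)herculeana_processionea:0.02,T_solitaria:0.07)cladeA:0.04,(((T_pityocampa:0.03,T_pityocampa_ENA:0.03)pityocampa_group:0.02,T_wilkinsoni:0.04)cladeB:0.05,((T_ispartaensis:0.02,T_libanotica:0.02)ispartaensis_libanotica:0.01,(T_bonjeani:0.02,T_pinivora:0.02)bonjeani_pinivora:0.01)cladeC:0.04)cladeBC:0.03)thaumetopoea:0.05)thaumetopoeinae:0.06)noctuoidea:0.02)root;
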