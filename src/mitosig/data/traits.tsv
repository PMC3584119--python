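# Categorical life-history traits of processionary moths and outgroups.
# Best-effort encoding from published results narrative; "?" marks states
# that could not be established from the text (treated as missing by the
# parsimony reconstruction).
taxon	biogeography	host_plant_class	host_plant_family	foliage_age	foraging_type	tent	gregariousness	pupation_procession	pupation_site	overwintering	crested_front	tibia_spine	egg_scales_size	urticating_setae
T_herculeana	mediterranean	angiosperm	Cistaceae	young	nomadic	none	early_instars	present	soil	egg	present	present	small	present
T_processionea	continental	angiosperm	Fagaceae	young	central_place	temporary	whole_stage	absent	tent	egg	absent	absent	small	present
T_solitaria	irano_turanic	angiosperm	Anacardiaceae	young	patch_restricted	temporary	whole_stage	present	litter	egg	absent	absent	small	present
T_pityocampa	continental	gymnosperm	Pinaceae	mature	central_place	persistent	whole_stage	present	soil	larva	present	present	large	present
T_pityocampa_ENA	mediterranean	gymnosperm	Pinaceae	mature	central_place	persistent	whole_stage	present	soil	larva	present	present	large	present
T_wilkinsoni	mediterranean	gymnosperm	Pinaceae	mature	central_place	persistent	whole_stage	present	soil	larva	present	present	large	present
T_ispartaensis	irano_turanic	gymnosperm	Pinaceae	mature	patch_restricted	temporary	whole_stage	present	soil	egg	present	present	small	present
T_libanotica	irano_turanic	gymnosperm	Pinaceae	mature	patch_restricted	temporary	whole_stage	present	soil	egg	present	present	small	present
T_bonjeani	mediterranean	gymnosperm	Pinaceae	mature	patch_restricted	temporary	whole_stage	present	soil	egg	present	present	small	present
T_pinivora	continental	gymnosperm	Pinaceae	mature	patch_restricted	temporary	whole_stage	present	soil	egg	present	present	small	present
O_lunifer	?	angiosperm	Fabaceae	?	central_place	temporary	whole_stage	present	soil	egg	absent	absent	?	present
H_cunea	?	angiosperm	?	?	?	?	?	?	?	?	absent	absent	?	absent
L_dispar	?	angiosperm	?	?	?	?	?	?	?	?	absent	absent	?	absent
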