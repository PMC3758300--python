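taxon	rps19_duplication	rps19_pseudogene	rps19_loss	ndhF_ycf1_overlap
Amborella_trichopoda	0	0	0	0
Nuphar_advena	0	0	0	0
Chloranthus_spicatus	0	0	0	1
Drimys_granadensis	0	0	0	1
Piper_cenocladum	0	0	0	0
Magnolia_denudata	0	0	0	0
Ceratophyllum_demersum	0	0	1	0
Nandina_domestica	1	1	0	0
Acorus_americanus	0	0	0	0
Colocasia_esculenta	0	0	0	0
Cymbidium_aloifolium	1	0	0	0
Calamus_caryotoides	1	0	0	1
Phoenix_dactylifera	1	0	0	1
Bismarckia_nobilis	1	0	0	1
Pseudophoenix_vinifera	1	0	0	1
Chamaedorea_seifrizii	1	0	0	1
Cocos_nucifera	1	1	0	1
Elaeis_guineensis	1	0	0	1
Dasypogon_bromeliifolius	1	0	0	1
Kingia_australis	1	0	0	1
Typha_latifolia	1	0	0	0
Musa_acuminata	1	0	0	0
Alpinia_zerumbet	1	0	0	0
Heliconia_collinsiana	1	1	0	0
Xiphidium_caeruleum	0	0	1	0
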