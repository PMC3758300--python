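(Amborella_trichopoda,(Nuphar_advena,((Chloranthus_spicatus,((Drimys_granadensis,Piper_cenocladum),Magnolia_denudata)),((Ceratophyllum_demersum,Nandina_domestica),(Acorus_americanus,(Colocasia_esculenta,(Cymbidium_aloifolium,(((Calamus_caryotoides,((Phoenix_dactylifera,Bismarckia_nobilis),(Pseudophoenix_vinifera,(Chamaedorea_seifrizii,(Cocos_nucifera,Elaeis_guineensis))))),(Dasypogon_bromeliifolius,Kingia_australis)),(Typha_latifolia,((Musa_acuminata,(Alpinia_zerumbet,Heliconia_collinsiana)),Xiphidium_caeruleum))))))))));
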