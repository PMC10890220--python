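((Cyrtodactylus_sp_2n48,Cyrtodactylus_sp_2n34),((Hemidactylus_bowringii,Hemidactylus_platyurus),(Hemidactylus_turcicus,((Hemidactylus_flavoviridis,(Hemidactylus_brookii,(Hemidactylus_fasciatus,Hemidactylus_frenatus))),(Hemidactylus_mabouia,Hemidactylus_mercatorius)))));
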