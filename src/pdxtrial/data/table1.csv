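model_id,uicc,kras,combo_d28,combo_d59,tram_d28,tram_d59
BoC51,I,G12D,PD,PD,missing,missing
BoC64,IV,G12D,PD,missing,missing,missing
BoC109,IIIC,G13D,PD,missing,missing,missing
BoC117,IVA,G12D,PD,PD,PD,PD
BoC122,IIIB,G12D,PD,PD,PD,PD
BoC2,IV,G12D,SD,SD,PD,PD
BoC19,IIA,A146T,SD,missing,missing,missing
BoC56,IIA,G12C,SD,SD,missing,missing
BoC78,IIA,G12D,SD,SD,missing,missing
BoC136,n.d.,G12V,SD,SD,PD,PD
BoC9,IV,G12D,PR,PR,missing,missing
BoC14,IIA,A146T,PR,PR,missing,missing
BoC46,IIA,G13D,PR,missing,missing,missing
BoC47,IIIB,G12D,PR,PR,SD,SR
BoC80,IB,G12V,PR,PR,missing,missing
BoC105,IIIB,G12V,PR,PR,SD,SR
BoC130,IIIC,G12D,PR,PR,missing,missing
BoC137,IVB,G12D,PR,PR,PD,PD
BoC147,IIIB,G12A,PR,PR,SD,SD
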