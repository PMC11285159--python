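(Tcallichromus:8.0,(Lrelictus:6.0,((Pphil_Thamalakane:0.8,Pphil_LakeChila:0.8,Pphil_MbuluCreek:0.8,Pphil_LakeMweru:0.8):0.7,(Pmult_victoriae:0.9,Pmult_multicolor:0.9):0.7,Pnicholsi:2.2):1.2):2.2);
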