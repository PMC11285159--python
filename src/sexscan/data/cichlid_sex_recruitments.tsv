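# Independent recruitments of each linkage group as a sex chromosome in
# East African cichlids (published tabulation; B = unpaired B chromosome).
LG	COUNT
LG01	1
LG02	3
LG03	4
LG04	3
LG05	7
LG06	0
LG07	6
LG08	0
LG09	1
LG10	1
LG11	1
LG12	1
LG13	1
LG14	2
LG15	3
LG16	3
LG17	2
LG18	1
LG19	2
LG20	3
LG22	0
LG23	4
B	2
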