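# Approximate chromosome sizes (bp) for the cichlid reference karyotype used
# in the size-weighted Monte Carlo null. These are synthetic round-number
# approximations, not assembly lengths: the 21 ordinary autosomes span
# ~31.5-41.5 Mb and LG07 is ~2x the mean of the rest; the unpaired B
# chromosome is assigned the mean chromosome size. Replace with exact
# assembly lengths for production use.
CHROM	SIZE
LG01	38000000
LG02	36000000
LG03	41500000
LG04	34000000
LG05	35500000
LG06	37000000
LG07	70500000
LG08	33500000
LG09	35000000
LG10	32500000
LG11	36500000
LG12	38500000
LG13	33000000
LG14	37500000
LG15	38500000
LG16	35500000
LG17	39000000
LG18	34500000
LG19	31500000
LG20	33500000
LG22	35000000
LG23	36000000
B	37400000
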