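# Saccharomyces cerevisiae sacCer3 (R64-1-1) chromosome sizes and centromere midpoints,
# rounded down to 1 kb (1 monomer = 1 kb).
# chrom	length_kb	centromere_kb
chrI	230	151
chrII	813	238
chrIII	316	114
chrIV	1531	449
chrV	576	152
chrVI	270	148
chrVII	1090	496
chrVIII	562	105
chrIX	439	355
chrX	745	436
chrXI	666	440
chrXII	1078	150
chrXIII	924	268
chrXIV	784	628
chrXV	1091	326
chrXVI	948	555
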