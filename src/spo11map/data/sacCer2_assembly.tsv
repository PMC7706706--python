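# sacCer2 (S288C, SGD 2008) nuclear chromosome geometry.
# cen_mid: centromere midpoint; rDNA repeat locus annotated on chrXII.
chrom	length	cen_mid	rdna_start	rdna_end
chrI	230208	151523
chrII	813178	238265
chrIII	316617	114443
chrIV	1531919	449766
chrV	576869	152045
chrVI	270148	148568
chrVII	1090947	496979
chrVIII	562643	105644
chrIX	439885	355687
chrX	745742	436366
chrXI	666454	440187
chrXII	1078175	150887	451418	468993
chrXIII	924429	268090
chrXIV	784333	628816
chrXV	1091289	326643
chrXVI	948062	556015
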