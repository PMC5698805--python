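# Synthetic reconstruction of the three family-specific LOD>2 regions.
# The original genotype data (and hence the true region bounds) are not
# published; these intervals are chosen to span the reported tier-2
# variant positions. Coordinates are 1-based inclusive.
family	chrom	start	end	lod
757	12	7000000	10000000	2.95
911	5	138000000	139500000	2.36
1201	22	37500000	40000000	2.22
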