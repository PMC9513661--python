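# Synthetic stand-in catalogue of known post-transcriptional modification
# sites in the mitochondrial 12S and 16S rRNAs. Modification classes are the
# canonical ones (pseudouridine Psi, 5-methyluridine m5U, 1-methyladenosine
# m1A, N4-methylcytidine m4C, 5-methylcytidine m5C, N6,N6-dimethyladenosine
# m62A, 2'-O-methylguanosine Gm, 2'-O-methyluridine Um); positions are
# representative coordinates inside the packaged 12S (70-1024) and 16S
# (1094-2675) gene spans and are NOT curated experimental coordinates.
position	molecule	modification
498	12S	m5U
908	12S	m4C
910	12S	m5C
1005	12S	m62A
1006	12S	m62A
1538	16S	m1A
2239	16S	Gm
2463	16S	Um
2491	16S	Gm
2517	16S	Psi
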