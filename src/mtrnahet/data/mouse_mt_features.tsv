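# translation_table=2
name	ftype	start	end	strand	frame
tRNA-Phe	tRNA	1	68	+	.
mt-Rnr1	rRNA	70	1024	+	.
tRNA-Val	tRNA	1025	1093	+	.
mt-Rnr2	rRNA	1094	2675	+	.
tRNA-Leu1	tRNA	2676	2750	+	.
mt-Nd1	protein_coding	2751	3707	+	0
tRNA-Ile	tRNA	3706	3774	+	.
tRNA-Gln	tRNA	3772	3842	-	.
tRNA-Met	tRNA	3845	3913	+	.
mt-Nd2	protein_coding	3914	4951	+	0
tRNA-Trp	tRNA	4950	5016	+	.
tRNA-Ala	tRNA	5018	5086	-	.
tRNA-Asn	tRNA	5089	5159	-	.
tRNA-Cys	tRNA	5192	5257	-	.
tRNA-Tyr	tRNA	5258	5326	-	.
mt-Co1	protein_coding	5328	6872	+	0
tRNA-Ser1	tRNA	6870	6938	-	.
tRNA-Asp	tRNA	6942	7011	+	.
mt-Co2	protein_coding	7013	7696	+	0
tRNA-Lys	tRNA	7700	7764	+	.
mt-Atp8	protein_coding	7766	7969	+	0
mt-Atp6	protein_coding	7927	8607	+	0
mt-Co3	protein_coding	8607	9390	+	0
tRNA-Gly	tRNA	9391	9458	+	.
mt-Nd3	protein_coding	9459	9806	+	0
tRNA-Arg	tRNA	9808	9875	+	.
mt-Nd4l	protein_coding	9877	10173	+	0
mt-Nd4	protein_coding	10167	11544	+	0
tRNA-His	tRNA	11546	11614	+	.
tRNA-Ser2	tRNA	11615	11673	+	.
tRNA-Leu2	tRNA	11674	11742	+	.
mt-Nd5	protein_coding	11742	13565	+	0
mt-Nd6	protein_coding	13552	14070	-	0
tRNA-Glu	tRNA	14071	14139	-	.
mt-Cytb	protein_coding	14145	15288	+	0
tRNA-Thr	tRNA	15289	15355	+	.
tRNA-Pro	tRNA	15356	15422	-	.
D-loop	D_loop	15443	16299	+	.
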