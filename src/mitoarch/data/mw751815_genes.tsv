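gene	strand	start	end	size	anticodon	start_codon	stop_codon
trnF	+	1	66	66	GAA	.	.
rrnS	+	66	1013	948	.	.	.
trnV	+	1018	1084	67	TAC	.	.
rrnL	+	1085	2655	1571	.	.	.
trnL2	+	2656	2730	75	TAA	.	.
nad1	+	2733	3689	957	.	ATG	TAG
trnI	+	3688	3756	69	GAT	.	.
trnQ	-	3754	3824	71	TTG	.	.
trnM	+	3824	3892	69	CAT	.	.
nad2	+	3893	4936	1044	.	ATC	TAG
trnW	+	4935	5001	67	TCA	.	.
trnA	-	5006	5075	70	TGC	.	.
trnN	-	5077	5149	73	GTT	.	.
trnC	-	5183	5249	67	GCA	.	.
trnY	-	5250	5315	66	GTA	.	.
cox1	+	5317	6864	1548	.	ATG	AGA
trnS2	-	6860	6928	69	TGA	.	.
trnD	+	6933	7001	69	GTC	.	.
cox2	+	7002	7685	684	.	ATG	TAG
trnK	+	7687	7750	64	TTT	.	.
atp8	+	7753	7956	204	.	ATG	TAA
atp6	+	7914	8594	681	.	ATG	TAA
cox3	+	8594	9379	786	.	ATG	TAA
trnG	+	9379	9445	67	TCC	.	.
nad3	+	9455	9802	348	.	ATT	TAG
trnR	+	9793	9858	66	TCG	.	.
nad4l	+	9860	10156	297	.	ATG	TAA
nad4	+	10150	11527	1378	.	ATG	T(AA)
trnH	+	11528	11596	69	GTG	.	.
trnS1	+	11597	11655	59	GCT	.	.
trnL1	+	11655	11724	70	TAG	.	.
nad5	+	11716	13536	1821	.	ATA	TAG
nad6	-	13539	14060	522	.	ATG	AGG
trnE	-	14061	14128	68	TTC	.	.
cob	+	14132	15271	1140	.	ATG	TAG
trnT	+	15271	15338	68	TGT	.	.
trnP	-	15340	15407	68	TGG	.	.
CR	.	15408	17164	1757	.	.	.
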