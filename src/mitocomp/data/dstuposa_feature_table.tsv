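Gene name	Start	Stop	Strand	Length	Anticodon	Start codon	End codon	Intergenic nucleotides
trnM	1	68	J	68	CAT	/	/	2
trnI	71	138	J	68	GAT	/	/	8
trnQ	147	215	N	69	TTG	/	/	55
nad2	271	1,284	J	1,014	/	ATT	TAA	-2
trnW	1,283	1,350	J	68	TCA	/	/	-8
trnC	1,343	1,409	N	67	GCA	/	/	22
trnY	1,432	1,496	N	65	GTA	/	/	9
cox1	1,506	3,041	J	1,536	/	CGA	TAA	-5
trnL2	3,037	3,103	J	67	TAA	/	/	0
cox2	3,104	3,820	J	717	/	ATA	TAA	-35
trnK	3,786	3,856	J	71	CTT	/	/	0
trnD	3,857	3,923	J	67	GTC	/	/	0
atp8	3,924	4,085	J	162	/	ATC	TAA	-7
atp6	4,079	4,756	J	678	/	ATG	TAA	27
cox3	4,784	5,572	J	789	/	ATG	TAA	2
trnG	5,575	5,640	J	66	TCC	/	/	0
nad3	5,641	5,994	J	354	/	ATT	TAA	34
trnA	6,029	6,085	J	57	TGC	/	/	105
trnR	6,191	6,256	J	66	TCG	/	/	10
trnN	6,267	6,332	J	66	GTT	/	/	8
trnS1	6,341	6,406	J	66	GCT	/	/	32
trnE	6,439	6,506	J	68	TTC	/	/	50
trnF	6,557	6,624	N	68	GAA	/	/	-17
nad5	6,608	8,368	N	1,761	/	ATT	TAA	-3
trnH	8,366	8,433	N	68	GTG	/	/	0
nad4	8,434	9,772	N	1,338	/	ATG	TA	42
nad4l	9,815	10,102	N	288	/	ATG	TAA	14
trnT	10,117	10,181	J	65	TGT	/	/	0
trnP	10,182	10,246	N	65	TGG	/	/	7
nad6	10,254	10,784	J	531	/	ATT	TAA	14
cob	10,799	11,959	J	1,161	/	ATG	TAA	-2
trnS2	11,958	12,025	J	68	TGA	/	/	22
nad1	12,048	12,986	N	939	/	ATG	TAA	1
trnL1	12,988	13,055	N	68	TAG	/	/	65
rrnL	13,121	14,428	N	1,308	/	/	/	37
trnV	14,466	14,533	N	68	TAC	/	/	0
rrnS	14,534	15,315	N	782	/	/	/	0
AT_rich	15,316	15,721	/	406	/	/	/	/
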