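Gene	Start	End	Strand	Size	StartCodon	StopCodon	Anticodon
cox1	1	1557	+	1557	GTG	AGA	-
trnS2	1553	1623	-	71	-	-	TGA
trnD	1627	1698	+	72	-	-	GTC
cox2	1712	2402	+	691	ATG	T	-
trnK	2403	2475	+	73	-	-	TTT
atp8	2477	2644	+	168	ATG	TAA	-
atp6	2635	3318	+	684	ATG	TAA	-
cox3	3318	4103	+	786	ATG	TAA	-
trnG	4103	4173	+	71	-	-	TCC
nad3	4174	4524	+	351	ATG	TAG	-
trnR	4523	4591	+	69	-	-	TCG
nad4l	4592	4888	+	297	ATG	TAA	-
nad4	4882	6262	+	1381	ATG	T	-
trnH	6263	6331	+	69	-	-	GTG
trnS1	6332	6399	+	68	-	-	GCT
trnL1	6401	6473	+	73	-	-	TAG
nad5	6474	8312	+	1839	ATG	TAA	-
nad6	8308	8829	-	522	ATG	AGG	-
trnE	8830	8898	-	69	-	-	TTC
cob	8905	10045	+	1141	ATG	T	-
trnT	10046	10117	+	72	-	-	TGT
trnP	10122	10191	-	70	-	-	TGG
trnF	11054	11121	+	68	-	-	GAA
rrnS	11122	12070	+	949	-	-	-
trnV	12071	12142	+	72	-	-	TAC
rrnL	12170	13814	+	1645	-	-	-
trnL2	13839	13912	+	74	-	-	TAA
nad1	13913	14887	+	975	ATG	TAA	-
trnI	14892	14961	+	70	-	-	GAT
trnQ	14961	15031	-	71	-	-	TTG
trnM	15031	15100	+	70	-	-	CAT
nad2	15101	16147	+	1047	ATG	TAA	-
trnW	16147	16219	+	73	-	-	TCA
trnA	16221	16289	-	69	-	-	TGC
trnN	16291	16363	-	73	-	-	GTT
trnC	16397	16461	-	65	-	-	GCA
trnY	16462	16529	-	68	-	-	GTA
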