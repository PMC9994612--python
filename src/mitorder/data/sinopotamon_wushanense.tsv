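#taxon=Sinopotamon_wushanense length=16785 circular=true
gene	start	end	length	strand	start_codon	stop_codon
cox1	1	1539	1539	F	ATG	TAA
trnL2	1535	1599	65	F
cox2	1625	2306	682	F	ATG	T--
trnK	2295	2361	67	F
trnD	2363	2427	65	F
atp8	2428	2586	159	F	ATG	TAG
atp6	2583	3254	672	F	ATA	TAA
cox3	3254	4045	792	F	ATG	TAA
trnG	4051	4115	65	F
nad3	4113	4469	357	F	ATA	TAA
trnA	4470	4538	69	F
trnR	4541	4601	61	F
trnN	4602	4671	70	F
trnS1	4675	4740	66	F
trnE	4741	4810	70	F
trnH	4901	4964	64	R
trnF	4964	5027	64	R
nad5	5008	6729	1722	R	ATT	TAG
nad4	6796	8133	1338	R	ATG	TAA
nad4L	8127	8411	285	R	ATG	TAA
trnT	8432	8496	65	F
trnP	8497	8558	62	R
nad6	8561	9067	507	F	ATT	TAA
cob	9130	10248	1119	F	ATG	TAG
trnS2	10202	10271	70	F
nad1	10329	11267	939	R	ATA	TAA
trnL1	11294	11359	60	R
trnM	11676	11746	71	F
nad2	11747	12751	1005	F	ATG	TAA
trnW	12750	12813	64	F
trnC	12813	12874	62	R
trnY	12875	12942	68	R
rrnL	13299	14590	1292	R
trnV	14620	14692	73	R
trnQ	15033	15100	68	R
rrnS	15247	16086	840	R
CR	16087	16785	699	.
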