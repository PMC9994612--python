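#taxon=Sinopotamon_chishuiense length=17311 circular=true
gene	start	end	length	strand	start_codon	stop_codon
cox1	1	1539	1539	F	ATG	TAA
trnL2	1535	1598	64	F
cox2	1605	2339	735	F	ATG	TAG
trnK	2293	2358	66	F
trnD	2360	2425	66	F
atp8	2426	2584	159	F	ATG	TAG
atp6	2629	3252	624	F	ATT	TAA
cox3	3252	4043	792	F	ATG	TAA
trnG	4049	4123	75	F
nad3	4133	4477	345	F	ATA	TAA
trnA	4478	4544	67	F
trnR	4547	4607	61	F
trnN	4607	4672	66	F
trnS1	4677	4743	67	F
trnE	4744	4814	71	F
trnH	5177	5248	72	R
trnF	5250	5315	66	R
nad5	5296	6966	1671	R	ATT	TAG
nad4	7082	8416	1335	R	ATG	TAA
nad4L	8410	8685	276	R	ATA	TAA
trnT	8715	8779	65	F
trnP	8780	8846	67	R
nad6	8856	9353	498	F	ATT	TAA
cob	9353	10489	1137	F	ATG	TAA
trnS2	10488	10554	67	F
nad1	10707	11636	930	R	ATT	TAA
trnL1	11672	11737	66	R
trnM	11813	11884	72	F
nad2	11906	12898	993	F	ATT	TAA
trnW	12889	12949	61	F
trnC	12949	13010	62	R
trnY	13011	13075	65	R
rrnL	13284	14644	1361	R
trnV	14665	14738	74	R
trnQ	14830	14899	70	R
rrnS	15174	16004	831	R
CR	16005	17120	1116	.
trnI	17121	17191	71	F
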