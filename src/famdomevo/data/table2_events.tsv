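lineage	canonical_name	branch_length	fam_birth	fam_death	dom_birth	dom_death	ufam_dup	ufam_del	udom_dup	udom_del
Hsa	Hsa	0.05	177	129	39	42	251	706	950	4208
Mmu	Mmu	0.06	106	96	27	48	245	668	709	4165
((Tsp (Cbr Cel)) ((Bmo (Aae Dme)) (Gga (Hsa Mmu))))	Aae,Bmo,Cbr,Cel,Dme,Gga,Hsa,Mmu,Tsp	0.16	1274	59	645	76	1789	369	7541	1760
(Tsp (Cbr Cel))	Cbr,Cel,Tsp	0.13	147	548	21	303	102	2816	284	11139
((Bmo (Aae Dme)) (Gga (Hsa Mmu)))	Aae,Bmo,Dme,Gga,Hsa,Mmu	0.09	805	36	175	27	474	1576	2538	5220
(Cbr Cel)	Cbr,Cel	0.55	4564	379	91	159	658	1060	2118	3508
Tsp	Tsp	0.62	1087	932	15	614	436	1506	1000	5778
Cbr	Cbr	0.09	520	81	24	102	145	299	781	1264
Cel	Cel	0.09	295	51	31	91	174	319	1100	1044
(Bmo (Aae Dme))	Aae,Bmo,Dme	0.18	725	446	37	261	695	1593	2104	7310
(Gga (Hsa Mmu))	Gga,Hsa,Mmu	0.33	2113	255	348	89	1567	2126	8494	7548
(Aae Dme)	Aae,Dme	0.14	452	205	13	78	137	758	396	2583
Bmo	Bmo	0.38	273	574	34	394	270	1675	615	6864
Aae	Aae	0.28	346	363	28	328	652	1040	1693	4114
Dme	Dme	0.33	249	357	52	116	368	961	999	3472
(Hsa Mmu)	Hsa,Mmu	0.09	1144	50	123	32	304	329	1132	1409
Gga	Gga	0.12	60	487	24	342	87	1346	262	7607
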