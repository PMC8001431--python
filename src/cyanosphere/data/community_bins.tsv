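metagenome	bin_id	completeness	contamination	contigs	size_bp	coverage	classification	tax_level	is_host
Stigonema_ocellatum	so01	99.28	2.35	515	10519008	471.84	Stigonema ocellatum	s	yes
Stigonema_ocellatum	so02	96.00	3.33	106	3017240	415.54	Sphingomonadaceae	f	no
Stigonema_ocellatum	so03	100.0	0.74	184	7762495	244.90	Spirosoma sp.	g	no
Stigonema_ocellatum	so04	80.80	5.34	36	4445593	244.15	Devosia sp.	g	no
Stigonema_ocellatum	so05	86.21	33.89	69	4652777	242.25	Bradyrhizobiaceae	f	no
Stigonema_ocellatum	so06	99.59	8.90	28	4785235	219.72	Sphingomonadaceae	f	no
Stigonema_ocellatum	so08	98.44	2.23	36	6359601	149.04	Comamonadaceae	f	no
Stigonema_ocellatum	so09	93.10	36.99	134	7299278	143.94	Sphingomonadaceae	f	no
Stigonema_ocellatum	so10	83.92	3.82	94	8160230	142.77	Rhizobiales	o	no
Stigonema_ocellatum	so11	98.10	0.71	62	4257773	122.35	Sphingobacteriaceae	f	no
Stigonema_ocellatum	so12	99.17	2.73	79	7053193	106.66	Pseudonocardiaceae	f	no
Stigonema_ocellatum	so13	99.66	0.63	53	3680574	98.53	Sphingopyxis sp.	g	no
Stigonema_ocellatum	so14	97.81	0.27	28	2624238	94.72	Microbacteriaceae	f	no
Stigonema_ocellatum	so16	100.00	0.13	33	6260391	74.38	Mycobacterium sp.	g	no
Stigonema_ocellatum	so18	99.51	1.08	49	6025211	61.24	Chitinophagaceae	f	no
Stigonema_ocellatum	so21	92.52	2.80	114	7675694	41.20	Comamonadaceae	f	no
Stigonema_ocellatum	so22	98.46	2.72	19	4521530	41.19	Bacteria	k	no
Stigonema_ocellatum	so23	95.26	0.00	148	3446731	41.02	Actinobacteria	p	no
Chlorogloea_purpurea	cp01_02	100.00	0.29	186	4595485	654.42	Chlorogloea purpurea	s	yes
Chlorogloea_purpurea	cp03	85.86	5.70	131	4964628	288.68	Comamonadaceae	f	no
Chlorogloea_purpurea	cp04	97.04	0.52	37	4500700	230.28	Chitinophagaceae	f	no
Chlorogloea_purpurea	cp05	81.59	14.77	93	4443934	150.84	Sphingomonadales	o	no
Chlorogloea_purpurea	cp06	98.12	30.88	130	6184863	105.77	Proteobacteria	p	no
Chlorogloea_purpurea	cp07	91.03	2.30	81	7916241	87.81	Planctomycetaceae	f	no
Chlorogloea_purpurea	cp10	89.39	25.52	79	8815014	60.85	Rhizobiales	o	no
Chlorogloea_purpurea	cp11	85.54	10.13	48	4001378	52.94	Sphingopyxis sp.	g	no
Chlorogloea_purpurea	cp12	93.73	34.01	91	8062010	45.99	Bosea sp.	g	no
Chlorogloea_purpurea	cp13	89.40	17.80	58	3664549	37.48	Sphingopyxis sp.	g	no
Chlorogloea_purpurea	cp14	99.09	1.75	36	3405585	31.73	Sphingomonadaceae	f	no
Chlorogloea_purpurea	cp15	97.62	0.98	33	4008507	28.58	Bacteria	k	no
Chlorogloea_purpurea	cp16	100.0	13.79	72	5989586	25.63	Luteitalea pratensis	s	no
Gomphosphaeria_aponina	ga03	97.82	0.11	746	5354489	85.91	Gomphosphaeria aponina	s	yes
Gomphosphaeria_aponina	ga04	100.00	5.55	277	4200065	58.22	Hyphomonas sp.	g	no
Gomphosphaeria_aponina	ga05	94.48	4.22	247	2796749	49.08	Brevundimonas sp.	g	no
Gomphosphaeria_aponina	ga06	99.53	1.40	378	4670292	34.15	Hydrogenophaga sp.	g	no
Gomphosphaeria_aponina	ga07	98.54	2.51	174	3619276	29.06	Rhizobiales	o	no
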