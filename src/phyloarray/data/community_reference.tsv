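group	phylum_or_order	hc_mean	hc_sd	cd_mean	cd_sd	gram	flagella	gc_percent
Propionibacterium	Actinobacteria	0.80	0.90	1.43	1.31	G+	N	60
Bifidobacterium	Actinobacteria	0.52	0.60	0.75	0.98	G+	N	61
Streptococcus mitis et rel	Bacilli	13.66	11.64	19.35	12.95	G+	N	40
Streptococcus bovis et rel	Bacilli	9.21	10.79	5.72	3.99	G+	N	37
Streptococcus intermedius et rel	Bacilli	6.38	5.00	7.64	5.12	G+	N	38
Gemella	Bacilli	1.47	2.27	1.77	2.54	G+	N	31
Enterococcus	Bacilli	0.28	0.33	0.19	0.22	G+	Y/N	38
Granulicatella	Bacilli	0.24	0.27	0.23	0.28	G+	N	37
Bacillus	Bacilli	0.17	0.46	0.01	0.01	G+	Y/N	38
Aerococcus	Bacilli	0.16	0.19	0.15	0.19	G+	N	41
Prevotella melaninogenica et rel	Bacteroidetes	5.29	4.02	6.51	9.75	G-	N	41
Allistipes et rel	Bacteroidetes	2.03	2.81	2.02	3.37	G-	N	55
Parabacteroides distasonis et rel	Bacteroidetes	1.76	2.34	1.21	2.23	G-	N	45
Bacteroides vulgatus et rel	Bacteroidetes	0.92	1.43	0.47	0.88	G-	N	42
Tannerella et rel	Bacteroidetes	0.88	1.38	0.60	1.08	G-	N	47
Bacteroides splachnicus et rel	Bacteroidetes	0.79	0.69	1.60	2.73	G-	N	43
Prevotella tannerae et rel	Bacteroidetes	0.76	1.10	0.51	0.64	G-	N	47
Prevotella oralis et rel	Bacteroidetes	0.32	0.29	0.16	0.19	G-	N	45
Bacteroides intestinalis et rel	Bacteroidetes	0.32	0.49	0.20	0.29	G-	N	43
Prevotella ruminicola et rel	Bacteroidetes	0.29	0.64	0.11	0.14	G-	N	48
Bacteroides plebeius et rel	Bacteroidetes	0.25	0.30	0.44	0.69	G-	N	44
Bacteroides stercoris et rel	Bacteroidetes	0.17	0.23	0.06	0.07	G-	N	46
Bacteroides ovatus et rel	Bacteroidetes	0.16	0.23	0.08	0.12	G-	N	42
Bacteroides fragilis et rel	Bacteroidetes	0.10	0.13	0.15	0.28	G-	N	44
Clostridia	Clostridium cl. I	0.30	0.78	0.01	0.01	G+	Y/N	26
Clostridium stercorarium et rel	Clostridium cl. III	0.14	0.23	0.03	0.08	G+	Y	39
Clostridium orbiscindens et rel	Clostridium cl. IV	1.14	1.69	0.19	0.17	G+	Y	57
Sporobacter termitidis et rel	Clostridium cl. IV	0.56	1.31	0.11	0.18	G+	Y	57
Clostridium leptum et rel	Clostridium cl. IV	0.50	1.07	0.13	0.14	G+	N	50
Anaerotruncus colihominis et rel	Clostridium cl. IV	0.15	0.41	4e-03	0.01	G+	N	54
Ruminococcus callidus et rel	Clostridium cl. IV	0.14	0.29	0.06	0.03	G+	N	43
Eubacterium siraeum et rel	Clostridium cl. IV	0.14	0.40	2e-03	0.01	G+	Y/N	45
Ruminococcus bromii et rel	Clostridium cl. IV	0.13	0.40	6e-07	2e-06	G+	N	41
Papillibacter cinnamivorans et rel	Clostridium cl. IV	0.13	0.28	0.01	0.01	G+	N	56
Veillonella	Clostridium cl. IX	2.36	1.78	2.61	3.40	G-	N	39
Clostridium difficile et rel	Clostridium cl. XI	0.13	0.21	0.06	0.02	G+	Y	29
Clostridium symbiosum et rel	Clostridium cl. XIVa	2.79	3.03	3.86	2.51	G+	Y	46
Ruminococcus obeum et rel	Clostridium cl. XIVa	1.79	2.28	1.48	0.91	G+	N	42
Bryantella formatexigens et rel	Clostridium cl. XIVa	0.90	1.34	0.24	0.11	G+	N	50
Coprococcus eutactus et rel	Clostridium cl. XIVa	0.81	1.50	0.21	0.16	G+	N	43
Dorea formicigenerans et rel	Clostridium cl. XIVa	0.75	1.07	0.25	0.13	G+	N	41
Butyrivibrio crossotus et rel	Clostridium cl. XIVa	0.48	1.12	0.08	0.09	G+	Y	38
Eubacterium rectale et rel	Clostridium cl. XIVa	0.47	0.76	0.62	0.53	G+	Y/N	41
Ruminococcus gnavus et rel	Clostridium cl. XIVa	0.28	0.51	0.09	0.04	G+	N	43
Lachnospira pectinoschiza et rel	Clostridium cl. XIVa	0.26	0.33	0.30	0.18	G+	Y	44
Clostridium sphenoides et rel	Clostridium cl. XIVa	0.20	0.44	0.09	0.17	G+	Y	42
Outgrouping Clostridium XIVa	Clostridium cl. XIVa	0.20	0.27	0.21	0.18	G+	Y	33
Anaerostipes caccae et rel	Clostridium cl. XIVa	0.10	0.17	0.07	0.09	G+	N	44
Eubacterium limosum et rel	Clostridium cl. XV	0.21	0.61	4e-03	0.01	G+	N	48
Solobacterium moorei et rel	Clostridium cl. XVI	0.52	1.02	0.04	0.11	G+	N	38
Sutterella wadsworthensis et rel	Proteobacteria	19.16	13.81	18.78	16.24	G-	N	62
Aquabacterium	Proteobacteria	9.61	7.08	9.45	9.20	G-	Y	66
Xanthomonadaceae	Proteobacteria	1.93	2.96	1.90	2.09	G-	Y	61
Moraxellaceae	Proteobacteria	1.19	1.13	1.33	1.06	G-	N	42
Vibrio	Proteobacteria	0.86	0.54	1.35	1.11	G-	Y	47
Escherichia coli et rel	Proteobacteria	0.61	0.65	0.50	0.33	G-	Y	51
Enterobacter aerogenes et rel	Proteobacteria	0.60	0.90	0.58	0.63	G-	Y	55
Burkholderia	Proteobacteria	0.45	0.45	0.56	0.47	G-	Y	65
Klebisiella pneumoniae et rel	Proteobacteria	0.40	0.27	0.74	0.50	G-	N	57
Oxalobacter formigenes et rel	Proteobacteria	0.29	0.29	0.29	0.33	G-	N	51
Haemophilus	Proteobacteria	0.25	0.17	0.46	0.31	G-	N	39
Pseudomonas	Proteobacteria	0.22	0.15	0.40	0.30	G-	Y	65
Proteus et rel	Proteobacteria	0.17	0.27	0.04	0.04	G-	Y	38
Serratia	Proteobacteria	0.10	0.07	0.20	0.15	G-	Y	56
Uncultured Mollicutes	Uncult. Mollicutes	0.20	0.49	0.03	0.02	G-	N	31
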