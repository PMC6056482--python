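study_id	first_author	year	country	ethnicity	resolution	n_cases	n_controls	platform
Jia2017_China	Jia	2017	China	Asian	allele_only	1201	4889	SNaPshot
Shankarappa2017_India	Shankarappa	2017	India	Asian	genotype	243	164	TaqMan
Huang2016_China	Huang	2016	China	Asian	allele_only	39	56	Sequenom
Luo2016_China	Luo	2016	China	Asian	genotype	109	120	PCR
Rezazadeh2016_Iran	Rezazadeh	2016	Iran	Asian	genotype	160	163	PCR
Wang2016_China	Wang	2016	China	Asian	genotype	748	760	SNaPshot
Jiao2015_China	Jiao	2015	China	Asian	genotype	229	318	PCR
Xiao2015_China_s1	Xiao	2015	China	Asian	allele_only	232	373	Sequenom
Xiao2015_China_s2	Xiao	2015	China	Asian	allele_only	227	378	Sequenom
Lu2014_China	Lu	2014	China	Asian	genotype	493	583	PCR
Chen2012_China	Chen	2012	China	Asian	genotype	451	338	Sequenom
Chung2012_Korea	Chung	2012	Korea	Asian	allele_only	290	544	TaqMan
Lin2012_China	Lin	2012	China	Asian	genotype	268	389	unknown
Ma2012_China	Ma	2012	China	Asian	genotype	127	143	PCR
Ohara2012_Japan	Ohara	2012	Japan	Asian	genotype	824	2933	Invader assay
Yu2010_China	Yu	2010	China	Asian	genotype	324	388	MALDI-TOF mass spectrometry
Seripa2017_Italy	Seripa	2017	Italy	Caucasian	genotype	520	569	PCR
Alaylioglu2016_Turkey	Alaylioglu	2016	Turkey	Caucasian	genotype	183	154	PCR
Montanola2016_Spain	Montanola	2016	Spain	Caucasian	allele_only	73	88	SNPlex
Ferrari2015_Italy	Ferrari	2015	Italy	Caucasian	allele_only	37	28	PCR
Sen2015_Turkey	Sen	2015	Turkey	Caucasian	genotype	112	106	TaqMan
Sleegers2015_Belgium	Sleegers	2015	Belgium	Caucasian	genotype	1295	1090	PCR
Carrasquillo2014_USA	Carrasquillo	2014	USA	Caucasian	genotype	54	2424	TaqMan
Pedraza2014_MCADRC_Caucasian	Pedraza	2014	MCADRC	Caucasian	allele_only	411	2145	TaqMan
Roussotte2014_ADNI	Roussotte	2014	ADNI	Caucasian	genotype	173	205	Illumina 610
Mullan2013_Ireland	Mullan	2013	Ireland	Caucasian	allele_only	154	142	TaqMan
Nizamutdinov2013_Russia	Nizamutdinov	2013	Russia	Caucasian	allele_only	166	128	ABI prism BigDye Terminator
Bettens2012_Belgium	Bettens	2012	Belgium	Caucasian	allele_only	954	810	PCR
Bettens2012_France	Bettens	2012	France	Caucasian	allele_only	1291	608	PCR
Bettens2012_Canada	Bettens	2012	Canada	Caucasian	allele_only	304	239	PCR
Kamboh2012_USA	Kamboh	2012	USA	Caucasian	genotype	1344	1350	TaqMan
Carrasquillo2010_USA	Carrasquillo	2010	USA	Caucasian	genotype	1819	2565	TaqMan
Corneveaux2010_NIA-MBB	Corneveaux	2010	NIA-MBB	Caucasian	allele_only	1019	591	Affymetrix 6.0
Golenkina2010_Russia	Golenkina	2010	Russia	Caucasian	genotype	534	702	PCR
Seshadri2010_Spain	Seshadri	2010	Spain	Caucasian	genotype	1140	1209	Illumina 550, 370, 300 and Affymetrix 500K
Giedraitis2009_Sweden	Giedraitis	2009	Sweden	Caucasian	genotype	79	365	Illumina GoldenGate
Harold2009_USA	Harold	2009	USA	Caucasian	genotype	1153	2187	Illumina 610, 550 and 300
Harold2009_UK-Ireland	Harold	2009	UK-Ireland	Caucasian	genotype	2220	4833	Illumina 610
Harold2009_Germany	Harold	2009	Germany	Caucasian	genotype	539	824	Illumina 610 and 550
Lambert2009_France	Lambert	2009	France	Caucasian	genotype	2039	5378	Illumina 610
Lambert2009_Italy	Lambert	2009	Italy	Caucasian	genotype	1480	1263	TaqMan and Sequenom
Lambert2009_Spain	Lambert	2009	Spain	Caucasian	genotype	748	810	TaqMan and Sequenom
Lambert2009_Belgium	Lambert	2009	Belgium	Caucasian	genotype	1035	491	TaqMan and Sequenom
Lambert2009_Finland	Lambert	2009	Finland	Caucasian	genotype	596	650	TaqMan and Sequenom
Pedraza2014_MCADRC_African	Pedraza	2014	MCADRC	African	allele_only	44	223	TaqMan
Belcavello2015_Brazil	Belcavello	2015	Brazil	American	genotype	81	161	PCR
Moreno2017_Colombia	Moreno	2017	Colombia	Mixed	allele_only	280	357	PCR
SantosReboucas2017_Brazil	Santos-Reboucas	2017	Brazil	Mixed	genotype	174	175	TaqMan
Ferrari2012_UK	Ferrari	2012	UK	Mixed	allele_only	342	277	TaqMan
Gu2011_Indiana	Gu	2011	Indiana	Mixed	genotype	106	98	PCR
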