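species	clade	genome_mb	loci	cpk_count
Aquilegia coerulea	dicot	302	24823	16
Arabidopsis thaliana	dicot	135	27416	34
Brachipodium distachyon	monocot	272	31694	27
Brassica rapa	dicot	283.8	40492	49
Capsella rubella	dicot	134.8	26521	32
Carica papaya	dicot	135	27332	15
Chlamydomonas reinhardtii	lower-eukaryote	111.1	17741	14
Citrus clememtina	dicot	301.4	24533	26
Citrus sinensis	dicot	319	25376	24
Coccomyxa subellipsoidea	lower-eukaryote	49	9629	2
Cucumis sativus	dicot	203	21494	18
Eucalyptus grandis	dicot	691	36376	22
Fragaria vesca	dicot	240	32831	14
Glycine max	dicot	975	54175	41
Gossipium raimondi	dicot	761.4	37505	40
Linum usitatissimum	dicot	318.3	43471	47
Malus domestica	dicot	881.3	63514	28
Manihot esculenta	dicot	532.5	34085	26
Medicago truncatula	dicot	241	50894	11
Micromonas pusila CCMP1545	lower-eukaryote	22	10660	2
Mimulus guttatus	dicot	321.7	26718	25
Oryza sativa	monocot	372	39049	30
Ostreococcus lucimarinus	lower-eukaryote	13.2	7796	3
Panicum virgatum	monocot	1358	98007	53
Phaseolus vulgaris	dicot	521.1	27197	25
Physcomitrella patens V.13	bryophyte	480	33362	25
Picea abies	gymnosperm	1960	28354	11
Populus trichocarpa	dicot	422.9	41335	28
Prunus persica	dicot	227.3	26873	17
Ricinus communis	dicot	400	31221	15
Selaginella moellendorffii	pteridophyte	212.5	22273	9
Setaria italica	monocot	405.7	35471	27
Solanum lycopersicum	dicot	900	34727	28
Solanum tubersum	dicot	800	35119	21
Sorghum bicolor	monocot	697.5	33032	28
Thellungiella halophila	dicot	238.5	26351	31
Theobroma cacao	dicot	346	29452	17
Vitis venifera	dicot	487	26346	17
Volvox carteri	lower-eukaryote	125.4	14971	6
Zea mays	monocot	2500	63540	47
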