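species	group	subgroup	chlL	chlN	chlB	por_count	accession
Cyanidioschyzon merolae	Rhodophyta	Bangiophyceae	-	-	-	3	NC_004799
Cyanidium caldarium	Rhodophyta	Bangiophyceae	-	-	-		NC_001840
Porphyra purpurea	Rhodophyta	Bangiophyceae	+	+	+	1	NC_000925
Pyropia haitanensis	Rhodophyta	Bangiophyceae	+	+	+	1	NC_021189
Pyropia yezoensis	Rhodophyta	Bangiophyceae	+	+	+	1	NC_007932
Calliarthron tuberculosum	Rhodophyta	Florideophyceae	+	+	+	1	NC_021075
Chondrus crispus	Rhodophyta	Florideophyceae	-	-	-	1	NC_020795
Gracilaria tenuistipitata var. liui	Rhodophyta	Florideophyceae	-	-	-	1	NC_006137
Gracilaria salicornia	Rhodophyta	Florideophyceae	-	-	-	1	KF861575
Grateloupia taiwanensis	Rhodophyta	Halymeniaceae	-	-	-		NC_021618
Porphyridium purpureum	Rhodophyta	Porphyridiophyceae	-	-	-	1	AP012987
Chroomonas mesostigmatica	Cryptophyta	Chroomonadaceae	+	ψ	?	2	EU233753; EU233756
Chroomonas pauciplastida	Cryptophyta	Chroomonadaceae	+	+	+	2	EU233754; EU233755; EU233748
Hemiselmis andersenii	Cryptophyta	Chroomonadaceae	+	+	+	2	EU233749; EU233750; EU233747
Hemiselmis tepida	Cryptophyta	Chroomonadaceae	+	+	?	2	EU233751; EU233752
Guillardia theta	Cryptophyta	Geminigeraceae	-	-	-	1	NC_000926
Rhodomonas salina	Cryptophyta	Pyrenomonadaceae	ψ	ψ	ψ	1-2	NC_009573
Emiliania huxleyi	Haptophyta	Isochrysidales	-	-	-	1	NC_007288
Pavlova lutheri	Haptophyta	Pavlovales	-	-	-	1-2	NC_020371
Phaeocystis antarctica	Haptophyta	Phaeocystales	-	-	-	2-3	NC_016703
Phaeocystis globosa	Haptophyta	Phaeocystales	-	-	-	2-3	NC_021637
Chrysochromulina tobin	Haptophyta	Prymnesiales	-	-	-	2	KJ201907
Fistulifera sp.	Stramenopila	Bacillariophyceae	-	-	-		NC_015403
Odontella sinensis	Stramenopila	Bacillariophyceae	-	-	-	2	NC_001713
Phaeodactylum tricornutum	Stramenopila	Bacillariophyceae	-	-	-	2	NC_008588
Synedra acus	Stramenopila	Bacillariophyceae	-	-	-		NC_016731
Thalassiosira oceanica	Stramenopila	Bacillariophyceae	-	-	-	2	NC_014808
Thalassiosira pseudonana	Stramenopila	Bacillariophyceae	-	-	-	2	NC_008589
Apedinella radians	Stramenopila	Dictyochophyceae	-	-	-		unpublished
Rhizochromulina marina	Stramenopila	Dictyochophyceae	+	+	+	1	unpublished
Nannochloropsis gaditana	Stramenopila	Eustigmatophyceae	+	+	+	1	KJ410682
Nannochloropsis oceanica	Stramenopila	Eustigmatophyceae	+	+	+	1	KJ410683
Nannochloropsis oculata	Stramenopila	Eustigmatophyceae	+	+	+	1	KJ410684
Nannochloropsis salina	Stramenopila	Eustigmatophyceae	+	+	+	1	KJ410685
Aureococcus anophagefferens	Stramenopila	Pelagophyceae	-	-	-	2	NC_012898
Aureoumbra lagunensis	Stramenopila	Pelagophyceae	+	+	+	1	NC_012903
Pelagomonas calceolata	Stramenopila	Pelagophyceae	-	-	-	2	unpublished
Desmarestia aculeata	Stramenopila	Phaeophyceae	+	+	?	1	unpublished
Ectocarpus siliculosus	Stramenopila	Phaeophyceae	+	+	+	1	NC_013498
Fucus vesiculosus	Stramenopila	Phaeophyceae	+	+	+		NC_016735
Nereocystis lutkeana	Stramenopila	Phaeophyceae	+	+	+		unpublished
Saccharina japonica	Stramenopila	Phaeophyceae	+	+	+		NC_018523
Pinguiococcus pyrenoidosus	Stramenopila	Pinguiophyceae	+	+	+	1	unpublished
Chattonella subsalsa	Stramenopila	Raphidophyceae	+	+	+	1	unpublished
Heterosigma akashiwo CCMP452	Stramenopila	Raphidophyceae	-	-	-	2	EU168191
Heterosigma akashiwo NIES293	Stramenopila	Raphidophyceae	-	-	-	2	NC_010772
Synura petersenii	Stramenopila	Synurophyceae	-	-	-		unpublished
Botrydium cytosum	Stramenopila	Xanthophyceae	+	+	+		unpublished
Tribonema aequale	Stramenopila	Xanthophyceae	+	+	+	1	unpublished
Vaucheria litorea	Stramenopila	Xanthophyceae	+	+	+	1	NC_011600
Durinskia baltica	Dinophyta	Dinotrichales	-	-	-		NC_014287
Kryptoperidinium foliaceum	Dinophyta	Dinotrichales	-	-	-		NC_014267
Chromera velia	Chromerida	Chromeraceae	-	-	-		NC_014340
Vitrella brassicaformis	Chromerida	Vitrellaceae	+,2	+,2	+	1	NC_014345
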