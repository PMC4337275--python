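species	group	subgroup	chlL	chlN	chlB	por_count	accession
Acutodesmus obliquus	Chlorophyta	Chlorophyceae	+	+	+		NC_008101
Chlamydomonas reinhardtii	Chlorophyta	Chlorophyceae	+	+	+	1	NC_005353
Dunaliella salina	Chlorophyta	Chlorophyceae	+	+	+		NC_016732
Floydiella terrestris	Chlorophyta	Chlorophyceae	+	+	+		NC_014346
Gonium pectorale	Chlorophyta	Chlorophyceae	+	+	+		NC_020438
Oedogonium cardiacum	Chlorophyta	Chlorophyceae	+	+	+		NC_011031
Pleodorina starrii	Chlorophyta	Chlorophyceae	+	+	+		NC_021109
Schizomeris leibleinii	Chlorophyta	Chlorophyceae	+	+	+		NC_015645
Stigeoclonium helveticum	Chlorophyta	Chlorophyceae	+	+	+		NC_008372
Micromonas pusilla	Chlorophyta	Mamiellophyceae	-	-	-	1	NC_012575
Monomastix sp.	Chlorophyta	Mamiellophyceae	-	-	-		NC_012101
Ostreococcus tauri	Chlorophyta	Mamiellophyceae	-	-	-	1	NC_008289
Nephroselmis olivacea	Chlorophyta	Nephroselmidophyceae	+,2	+,2	+,2		NC_000927
Pycnococcus provasolii	Chlorophyta	Prasinophyceae	+	+	-	1	NC_012097
Pyramimonas parkeae	Chlorophyta	Prasinophyceae	+,2	+,2	+	1	NC_012099
Chlorella variabilis	Chlorophyta	Trebouxiophyceae	+	+	+	1	NC_015359
Chlorella vulgaris	Chlorophyta	Trebouxiophyceae	+	+	+	1	NC_001865
Coccomyxa subellipsoidea	Chlorophyta	Trebouxiophyceae	+	+	+		NC_015084
Leptosira terrestris	Chlorophyta	Trebouxiophyceae	+	+	+		NC_009681
Parachlorella kessleri	Chlorophyta	Trebouxiophyceae	+	+	+		NC_012978
Pedinomonas minor	Chlorophyta	Trebouxiophyceae	-	-	-		NC_016733
Trebouxiophyceae sp.	Chlorophyta	Trebouxiophyceae	+	+	+		NC_018569
Bryopsis hypnoides	Chlorophyta	Ulvophyceae	+	+	+		NC_013359
Oltmannsiellopsis viridis	Chlorophyta	Ulvophyceae	+	+	+		NC_008099
Pseudendoclonium akinetum	Chlorophyta	Ulvophyceae	-	-	-		NC_008114
Bigelowiella natans	Cercozoa	Chlorarachniophyceae	-	-	-	3	NC_008408
Lotharella oceanica	Cercozoa	Chlorarachniophyceae	-	-	-	3	KF438023
Euglena gracilis	Euglenozoa	Euglenophyceae	-	-	-		NC_001603
Euglena viridis	Euglenozoa	Euglenophyceae	-	-	-		NC_020460
Eutreptiella gymnastica	Euglenozoa	Euglenophyceae	-	-	-	2	NC_017754
Monomorphina aenigmatica	Euglenozoa	Euglenophyceae	-	-	-		NC_020018
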