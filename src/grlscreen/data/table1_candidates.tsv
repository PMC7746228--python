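protein	kingdom	phylum	species	isolate	accession	trimmed
SpunGRL1	Fungi	Chytridiomycota	Spizellomyces punctatus	DAOM BR117	XP_016607089.1	no
SpalGRL1	Fungi	Chytridiomycota	Spizellomyces palustris	CBS 455.65	TPX68946.1	no
PfunGRL1	Protista	Amoebozoa	Protostelium aurantium var. fungivorum	-	PRP89608.1	no
TtraGRL1	Protista	Apusozoa	Thecamonas trahens	ATCC 50062	XP_013761079.1	no
TtraGRL2	Protista	Apusozoa	Thecamonas trahens	ATCC 50062	XP_013753662.1	no
TtraGRL3	Protista	Apusozoa	Thecamonas trahens	ATCC 50062	XP_013759733.1	yes
TtraGRL4	Protista	Apusozoa	Thecamonas trahens	ATCC 50062	XP_013759396.1	no
TtraGRL5	Protista	Apusozoa	Thecamonas trahens	ATCC 50062	XP_013757274.1	no
TtraGRL6	Protista	Apusozoa	Thecamonas trahens	ATCC 50062	XP_013755387.1	no
VbraGRL1	Protista	Chromerida	Vitrella brassicaformis	CCMP3315	CEM13019.1	no
VbraGRL2	Protista	Chromerida	Vitrella brassicaformis	CCMP3315	CEL93132.1	no
VbraGRL3	Protista	Chromerida	Vitrella brassicaformis	CCMP3315	CEM19221.1	no
VbraGRL4	Protista	Chromerida	Vitrella brassicaformis	CCMP3315	CEM01650.1	no
VbraGRL5	Protista	Chromerida	Vitrella brassicaformis	CCMP3315	CEM10760.1	no
VbraGRL6	Protista	Chromerida	Vitrella brassicaformis	CCMP3315	CEM25255.1	no
CpriGRL1	Plantae	Chlorophyta	Chloropicon primus	-	QDZ19318.1	no
MpusGRL1	Plantae	Chlorophyta	Micromonas pusilla	CCMP1545	XP_003054778.1	no
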