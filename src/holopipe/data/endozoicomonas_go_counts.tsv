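comparison	term	name	annotated	significant
vs_all	GO:0006259	DNA metabolic process	2124	803
vs_all	GO:0006313	transposition, DNA-mediated	450	216
vs_all	GO:0032196	transposition	450	216
vs_all	GO:0006310	DNA recombination	830	342
vs_all	GO:0046903	secretion	424	194
vs_all	GO:0009306	protein secretion	417	190
vs_all	GO:0032940	secretion by cell	417	190
vs_all	GO:0008643	carbohydrate transport	262	130
vs_all	GO:0006024	glycosaminoglycan biosynthetic process	21	21
vs_all	GO:0033036	macromolecule localization	808	320
vs_oceanospirillales	GO:0071702	organic substance transport	1220	648
vs_oceanospirillales	GO:0006259	DNA metabolic process	1687	803
vs_oceanospirillales	GO:0008643	carbohydrate transport	183	130
vs_oceanospirillales	GO:0006310	DNA recombination	629	342
vs_oceanospirillales	GO:0006313	transposition, DNA-mediated	357	216
vs_oceanospirillales	GO:0009401	phosphoenolpyruvate-dependent sugar phosphotransferase	107	86
vs_oceanospirillales	GO:0044765	single-organism transport	2661	1180
vs_oceanospirillales	GO:0098656	anion transmembrane transport	78	64
vs_oceanospirillales	GO:0006835	dicarboxylic acid transport	65	55
vs_oceanospirillales	GO:1903825	organic acid transmembrane transport	70	56
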