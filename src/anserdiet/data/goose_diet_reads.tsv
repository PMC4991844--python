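# Assigned read counts per food taxon and bird group from the trnL
# metabarcoding run (GWFG = greater white-fronted goose, BG = bean goose).
group	taxon	rank	n_reads
GWFG	Poaceae	family	51705
GWFG	Poa annua	species	23554
GWFG	Carex heterolepis	species	18867
GWFG	Carex	genus	9706
GWFG	Alopecurus aequalis	species	3458
GWFG	Potentilla chinensis	species	184
GWFG	Cynodon dactylon	species	155
GWFG	Polygonum	genus	56
GWFG	Stellaria media	species	26
GWFG	Ranunculus chinensis	species	14
GWFG	Lapsana apogonoides	species	11
GWFG	Asteraceae sp.	genus	16
BG	Poa annua	species	167
BG	Carex heterolepis	species	81457
BG	Carex	genus	191
BG	Potentilla chinensis	species	65
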