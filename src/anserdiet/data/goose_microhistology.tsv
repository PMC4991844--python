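# Microhistology food-item percentages (Fm, share of identifiable
# epidermis fragments) for the same fecal samples.
group	taxon	rank	fm_percent
GWFG	Poaceae	family	45.68
GWFG	Carex heterolepis	species	16.39
GWFG	Carex	genus	2.31
GWFG	Potentilla chinensis	species	1.18
GWFG	Asteraceae sp.	genus	2.33
GWFG	Alopecurus	genus	30.93
GWFG	Carex thunbergii	species	0.54
GWFG	Fabaceae sp.	genus	0.64
BG	Carex heterolepis	species	62.85
BG	Carex	genus	3.49
BG	Potentilla chinensis	species	2.06
BG	Asteraceae sp.	genus	14.55
BG	Alopecurus	genus	13.18
BG	Carex thunbergii	species	2.79
BG	Fabaceae sp.	genus	1.08
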