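# Reference-library taxonomy of the 70 morpho-species sampled at
# Shengjin Lake for the local trnL barcode library.
seq_id	family	genus	species
SJ001	Hypoxidaceae	Curculigo	Curculigo orchioides
SJ002	Asteraceae	Artemisia	Artemisia capillaris
SJ003	Asteraceae	Artemisia	Artemisia selengensis
SJ004	Asteraceae	Aster	Aster subulatus
SJ005	Asteraceae	Bidens	Bidens frondosa
SJ006	Asteraceae	Erigeron	Erigeron annuus
SJ007	Asteraceae	Gnaphalium	Gnaphalium affine
SJ008	Asteraceae	Hemistepta	Hemistepta lyrata
SJ009	Asteraceae	Kalimeris	Kalimeris incisa
SJ010	Boraginaceae	Bothriospermum	Bothriospermum kusnezowii
SJ011	Campanulaceae	Lobelia	Lobelia chinensis
SJ012	Caryophyllaceae	Sagina	Sagina japonica
SJ013	Caryophyllaceae	Stellaria	Stellaria media
SJ014	Convolvulaceae	Calystegia	Calystegia hederacea
SJ015	Brassicaceae	Cardamine	Cardamine lyrata
SJ016	Cyperaceae	Carex	Carex heterolepis
SJ017	Cyperaceae	Carex	Carex capricornis
SJ018	Cyperaceae	Carex	Carex paxii
SJ019	Cyperaceae	Carex	Carex remotiuscula
SJ020	Cyperaceae	Fimbristylis	Fimbristylis dichotoma
SJ021	Cyperaceae	Eleocharis	Eleocharis migoana
SJ022	Cyperaceae	Scripus	Scripus karuizawensis
SJ023	Menyanthaceae	Nymphoides	Nymphoides peltatum
SJ024	Haloragaceae	Myriophyllum	Myriophyllum spicatum
SJ025	Hydrocharitaceae	Hydrilla	Hydrilla verticillta
SJ026	Hydrocharitaceae	Hydrocharis	Hydrocharis dubia
SJ027	Hydrocharitaceae	Vallisneria	Vallisineria spiralis
SJ028	Hydrocharitaceae	Vallisneria	Vallisneria spinulosa
SJ029	Juncaceae	Juncus	Juncus effusus
SJ030	Juncaceae	Juncus	Juncus gracillimus
SJ031	Lamiaceae	Leonurus	Leonurus japonicus
SJ032	Lamiaceae	Salvia	Salvia plebeia
SJ033	Fabaceae	Glycine	Glycine soja
SJ034	Fabaceae	Vicia	Vicia sativa
SJ035	Nymphaeaceae	Euryale	Euryale ferox
SJ036	Pedaliaceae	Trapella	Trapella sinensis
SJ037	Plantaginaceae	Plantago	Plantago asiatica
SJ038	Poaceae	Alopecurus	Alopecurus aequalis
SJ039	Poaceae	Beckmannia	Beckmannia syzigachne
SJ040	Poaceae	Bromus	Bromus japonicus
SJ041	Poaceae	Cynodon	Cynodon dactylon
SJ042	Poaceae	Phalaris	Phalaris arundinacea
SJ043	Poaceae	Phragmites	Phragmites australis
SJ044	Poaceae	Poa	Poa annua
SJ045	Poaceae	Polypogon	Polypogon fugax
SJ046	Poaceae	Roegneria	Roegneria kamoji
SJ047	Poaceae	Zizania	Zizania latifolia
SJ048	Polygonaceae	Polygonum	Polygonum lapathifolium
SJ049	Polygonaceae	Polygonum	Polygonum orientale
SJ050	Polygonaceae	Polygonum	Polygonum perfoliatum
SJ051	Polygonaceae	Polygonum	Polygonum persicaria
SJ052	Polygonaceae	Rumex	Rumex trisetiferus
SJ053	Potamogetonaceae	Potamogeton	Potamogeton crispus
SJ054	Potamogetonaceae	Potamogeton	Potamogeton maackianus
SJ055	Potamogetonaceae	Potamogeton	Potamogeton malaianus
SJ056	Potamogetonaceae	Potamogeton	Potamogeton natans
SJ057	Potamogetonaceae	Potamogeton	Potamogeton pectinatus
SJ058	Ranunculaceae	Clematis	Clematis florida
SJ059	Ranunculaceae	Ranunculus	Ranunculus chinensis
SJ060	Ranunculaceae	Ranunculus	Ranunculus sceleratus
SJ061	Rosaceae	Potentilla	Potentilla freyniana
SJ062	Scrophulariaceae	Gratiola	Gratiola japonica
SJ063	Scrophulariaceae	Mazus	Mazus miquelii
SJ064	Scrophulariaceae	Veronica	Veronica undulata
SJ065	Trapaceae	Trapa	Trapa bispinosa
SJ066	Trapaceae	Trapa	Trapa maximowiczii
SJ067	Trapaceae	Trapa	Trapa pseudoincisa
SJ068	Trapaceae	Trapa	Trapa quadrispinosa
SJ069	Umbelliferae	Hydrocotyle	Hydrocotyle sibthorpioides
SJ070	Umbelliferae	Torilis	Torilis japonica
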