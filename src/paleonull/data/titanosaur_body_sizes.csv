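species,length_m
Adamantisaurus mezzalirai,
Aeolosaurus colhuehuapiensis,
Aeolosaurus rionegrinus,
Antarctosaurus wichmannianus,
Argyrosaurus superbus,
Atacamatitan chilensis,
Barrosasaurus casamiquelai,
Baurutitan britoi,
Bonitasaura salgadoi,
Bonatitan reigi,
Gondwanatitan faustoi,
Laplatasaurus araukanicus,
Maxakalisaurus topai,
Narambuenatitan palomoi,
Neuquensaurus australis,
Panamericansaurus schroederi,
Pellegrinisaurus powelli,
Pitekunsaurus macayai,
Puertasaurus reuili,30
Rocasaurus muniozi,8
Saltasaurus loricatus,
Trigonosaurus pricei,
Uberabatitan ribeiroi,
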