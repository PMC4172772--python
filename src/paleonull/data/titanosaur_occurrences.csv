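species,Adamantina,Anacleto,Angostura Colorada,Allen,Los Alamitos,Bajo Barreal,Marilia,Palacio,Plottier,Cambambe,Bajo de la Carpa,Pari Aike,Lecho,Tolar
Adamantisaurus mezzalirai,1,0,0,0,0,0,0,0,0,0,0,0,0,0
Aeolosaurus colhuehuapiensis,0,0,0,0,0,1,0,0,0,0,0,0,0,0
Aeolosaurus rionegrinus,0,0,1,0,1,0,0,0,0,0,0,0,0,0
Antarctosaurus wichmannianus,1,1,0,0,0,0,0,1,1,0,0,0,0,0
Argyrosaurus superbus,0,0,0,0,0,1,0,0,0,0,0,0,0,0
Atacamatitan chilensis,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Barrosasaurus casamiquelai,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Baurutitan britoi,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Bonitasaura salgadoi,0,0,0,0,0,0,0,0,0,0,1,0,0,0
Bonatitan reigi,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Gondwanatitan faustoi,1,0,0,0,0,0,0,0,0,1,0,0,0,0
Laplatasaurus araukanicus,0,1,0,1,0,0,0,1,0,0,0,0,0,0
Maxakalisaurus topai,1,0,0,0,0,0,0,0,0,0,0,0,0,0
Narambuenatitan palomoi,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Neuquensaurus australis,0,1,0,1,0,0,0,1,0,0,1,0,0,0
Panamericansaurus schroederi,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Pellegrinisaurus powelli,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Pitekunsaurus macayai,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Puertasaurus reuili,0,0,0,0,0,0,0,0,0,0,0,1,0,0
Rocasaurus muniozi,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Saltasaurus loricatus,0,0,0,0,0,0,0,0,0,0,0,0,1,0
Trigonosaurus pricei,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Uberabatitan ribeiroi,0,0,0,0,0,0,1,0,0,0,0,0,0,0
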