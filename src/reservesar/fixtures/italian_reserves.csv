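id,name,latitude,longitude,area_km2,elev_min_m,elev_max_m,elev_range_m,elev_mean_m,elev_min_m_alt,elev_max_m_alt,elev_range_m_alt,elev_mean_m_alt,richness.Carabidae,richness.Hydradephaga,richness.coprophagous_Scarabaeoidea,richness.phytophagous_Scarabaeoidea,richness.total_Scarabaeoidea,richness.Tenebrionidae
1,Val Grande National Park,46.03,8.48,146,400,2200,1820,1116.5,,,,,131,-,-,-,-,-
2,Vincheto di Celarda Nature Reserve,46.02,11.98,1,225,233,8,229,,,,,-,-,16,19,36,1
3,Ticino Regional Park,45.31,8.93,983,116,300,184,208,,,,,249,63,12,33,51,13
4,Bosco Fontana Nature Reserve,45.20,10.74,2.3,22,26,4,24,,,,,71,40,4,16,24,14
5,Isola Boscone Nature Reserve,45.04,11.24,1.3,7,15,8,14,,,,,-,-,0,5,6,6
6,Agoraie Nature Reserve,44.49,9.42,0.17,1326,1350,24,1330.5,,,,,23,10,0,5,5,-
7,Guadine Pradaccio Nature Reserve,44.40,10.02,2.9,1330,1470,140,1406.5,,,,,24,12,-,-,-,-
8,Foreste Casentinesi National Park,43.83,11.73,368.5,550,1200,650,868,350,1450,1106,753.5,198,48,-,-,-,-
9,Burano Nature Reserve,42.40,11.21,4,0,3,3,1.5,,,,,38,1,1,2,5,14
10,Pescara Spring Nature Reserve and adjacent areas in the Valle Peligna,42.16,13.82,100,300,400,100,350,,,,,87,-,14,13,28,16
11,Inviolata Archeological and Nature Park,41.98,12.67,5.4,50,120,70,85,,,,,77,13,22,12,37,13
12,Foce Saccione Site of Community Importance,41.93,15.11,9.6,0,1,1,0.5,,,,,-,-,-,-,-,10
13,"Abruzzo, Latium and Molise National Park",41.81,13.79,1040,700,2249,1549,1474.5,,,,,243,-,69,18,95,-
14,Gargano National Park and Isola Varano Nature Reserve,41.81,15.85,1700,0,950,950,456,,,,,233,55,70,25,105,61
15,Castelporziano Presidential Estate and Castelfusano Urban Park,41.70,12.38,70,0,70,70,35,,,,,179,69,62,27,104,44
16,Circeo National Park,41.34,13.04,88,0,541,541,270.5,,,,,-,34,-,-,-,36
17,Vulture Natural Park,40.95,15.63,66,650,1326,676,988,,,,,172,25,55,16,73,17
18,Vesuvius National Park,40.82,14.43,84.8,200,1281,1081,740.5,,,,,32,-,8,11,19,23
19,Pantano di Pignola Reserve,40.59,15.75,1.6,764,770,6,767,,,,,109,30,21,10,33,9
20,Policoro Reserve,40.18,16.70,5,0,6,6,3,,,,,253,69,54,28,97,58
21,Pollino National Park,39.97,16.21,1100,800,2000,1200,1482,,,,,220,56,75,29,106,35
22,Sila National Park,39.32,16.58,1250,1000,1900,900,1425,,,,,201,55,65,29,96,36
23,Madonie Regional Natural Park,37.89,14.00,399.4,400,1979,1579,1189.5,,,,,-,-,81,35,129,39
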