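province_id,name,region,zone,sampled
1,Parinacota,Arica y Parinacota,North,0
2,Arica,Arica y Parinacota,North,311
3,Iquique,Tarapaca,North,289
4,Tamarugal,Tarapaca,North,24
5,Tocopilla,Antofagasta,North,34
6,El Loa,Antofagasta,North,88
7,Antofagasta,Antofagasta,North,183
8,Chanaral,Atacama,North,0
9,Copiapo,Atacama,North,226
10,Huasco,Atacama,North,81
11,Elqui,Coquimbo,North,185
12,Limari,Coquimbo,North,72
13,Choapa,Coquimbo,North,49
14,San Antonio,Valparaiso,Center,34
15,Petorca,Valparaiso,Center,17
16,Valparaiso,Valparaiso,Center,187
17,Quillota,Valparaiso,Center,48
18,Los Andes,Valparaiso,Center,25
19,San Felipe de Aconcagua,Valparaiso,Center,34
20,Chacabuco,Metropolitana,Center,13
21,Santiago,Metropolitana,Center,728
22,Melipilla,Metropolitana,Center,26
23,Talagante,Metropolitana,Center,18
24,Maipo,Metropolitana,Center,49
25,Cordillera,Metropolitana,Center,77
26,Cardenal Caro,OHiggins,Center,0
27,Cachapoal,OHiggins,Center,211
28,Colchagua,OHiggins,Center,102
29,Cauquenes,Maule,Center,19
30,Curico,Maule,Center,85
31,Linares,Maule,Center,108
32,Talca,Maule,Center,139
33,Arauco,Biobio,Center,51
34,Concepcion,Biobio,Center,134
35,Nuble,Biobio,Center,57
36,Biobio,Biobio,Center,49
37,Malleco,Araucania,South,67
38,Cautin,Araucania,South,261
39,Ranco,Los Rios,South,71
40,Valdivia,Los Rios,South,228
41,Chiloe,Los Lagos,South,74
42,Llanquihue,Los Lagos,South,151
43,Palena,Los Lagos,South,0
44,Osorno,Los Lagos,South,92
45,Coyhaique,Aysen,Far South,185
46,General Carrera,Aysen,Far South,98
47,Aysen,Aysen,Far South,0
48,Capitan Prat,Aysen,Far South,0
49,Antartica Chilena,Magallanes,Far South,0
50,Ultima Esperanza,Magallanes,Far South,56
51,Magallanes,Magallanes,Far South,243
52,Tierra del Fuego,Magallanes,Far South,14
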