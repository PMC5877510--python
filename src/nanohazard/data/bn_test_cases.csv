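case,shape,nanoparticle,dissolution,surface_area,surface_charge,surface_coatings,surface_reactivity,aggregation,particle_size,administration_route,study_type,actual,predicted
1,Irregular,TiO2,0-25%,51-101.25,from -50 to -25,Silianes-aluminium,Low,High,10-50,-,In vitro,None,None
2,Amorph,TiO2,-,-,-,-,-,-,>100,Injection,In vivo,High,Medium
3,Sphere,TiO2,-,-,-,AHPP,-,Low,10-50,-,In vitro,None,None
4,Irregular,TiO2,-,15-51,-,-,-,High,>100,Oral,In vivo,None,Medium
5,Irregular,TiO2,-,51-101.25,from -50 to -25,Hydroxyl,-,Medium,50-100,Oral,In vivo,None,Low
6,Sphere,Ag,-,-,-,-,-,-,10-50,Inhalation,In vivo,High,High
7,Sphere,Ag,-,-,-,PVP,-,Low,50-100,Inhalation,In vivo,High,Medium
8,Sphere,Ag,-,-,-,-,-,-,10-50,Intravenous,In vivo,None,None
9,Sphere,Ag,-,-,-,Citrate,-,-,10-50,Oral,In vivo,Medium,Medium
10,Sphere,Ag,-,0-15,from -50 to -25,PVP,-,High,10-50,-,In vitro,None,Low
11,Sphere,Ag,0-25%,-,-,-,-,Low,10-50,Oral,In vivo,Medium,Medium
12,Sphere,Ag,-,-,0-25,-,-,Low,10-50,Oral,In vivo,High,Medium
13,Elongated,ZnO,-,0-15,0-25,None,-,Medium,>100,-,In vitro,High,High
14,Elongated,ZnO,0-25%,15-51,-,Triethoxycapryl silane,-,Medium,>100,-,In vitro,High,High
15,Irregular,ZnO,0-25%,-,-,-,Low,-,10-50,-,In vitro,High,High
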