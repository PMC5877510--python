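loe_id,reference,nm,s_pchem,s_tox,s_total,quality_weight,weight_norm,weighted_index
1,Baisch et al.,TiO2,41.67,87.50,73.75,0.61,0.04,3.24
2,Baisch et al.,TiO2,41.67,75.00,65.00,0.84,0.06,3.91
3,Baisch et al.,TiO2,50.00,75.00,67.50,0.84,0.06,4.06
4,Catalan et al.,TiO2,38.89,37.50,37.92,0.71,0.05,1.94
5,Catalan et al.,TiO2,38.89,62.50,55.42,0.79,0.06,3.13
6,Catalan et al.,TiO2,38.89,37.50,37.92,0.65,0.05,1.78
7,Chen et al.,TiO2,30.56,75.00,61.67,0.48,0.03,2.14
8,Duan et al.,TiO2,44.44,25.00,30.83,0.47,0.03,1.04
9,Duan et al.,TiO2,44.44,25.00,30.83,0.32,0.02,0.71
10,Farcal et al.,TiO2,61.11,25.00,35.83,0.77,0.06,1.99
11,Farcal et al.,TiO2,47.22,37.50,40.42,0.76,0.05,2.20
12,Fisichella et al.,TiO2,30.56,12.50,17.92,0.52,0.04,0.66
13,Fisichella et al.,TiO2,38.89,12.50,20.42,0.56,0.04,0.81
14,Gurr et al.,TiO2,33.33,62.50,53.75,0.50,0.04,1.94
15,Gurr et al.,TiO2,33.33,37.50,36.25,0.50,0.04,1.31
16,Hu et al.,TiO2,47.22,62.50,57.92,0.54,0.04,2.23
17,Leppanen et al.,TiO2,41.67,12.50,21.25,0.62,0.04,0.95
18,Lindberg et al.,TiO2,41.67,0.00,12.50,0.63,0.05,0.57
19,Lindberg et al.,TiO2,41.67,50.00,47.50,0.56,0.04,1.91
20,Shimizu et al.,TiO2,33.33,62.50,53.75,0.76,0.05,2.93
21,Tassinari et al.,TiO2,52.78,12.50,24.58,0.56,0.04,0.98
22,Wang et al.,TiO2,41.67,62.50,56.25,0.94,0.07,3.80
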