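id,name,habitat,n_species,n_basal,n_links,q,temperature
1,Broad Stream,River,94,53,564,0.14,0.37
2,Sutton Stream (Autumn),River,80,49,335,0.15,0.40
3,Stony Stream,River,109,61,827,0.15,0.38
4,Canton Creek,River,102,54,696,0.15,0.38
5,Akatore Stream,River,84,43,227,0.16,0.40
6,Crystal Lake (Delta),Lake,19,3,30,0.17,0.43
7,Berwick Stream,River,77,35,240,0.18,0.40
8,Kyeburn Stream,River,98,58,629,0.18,0.41
9,Blackrock Stream,River,86,49,375,0.19,0.42
10,Troy Stream,River,77,40,181,0.19,0.42
11,German Stream,River,84,48,352,0.20,0.43
12,Caitlins Stream,River,48,14,110,0.20,0.41
13,Dempsters Stream (Autumn),River,83,46,414,0.21,0.43
14,Powder Stream,River,78,32,268,0.22,0.42
15,Healy Stream,River,96,47,634,0.22,0.42
16,Venlaw Stream,River,66,30,187,0.23,0.44
17,Narrowdale Stream,River,71,28,154,0.23,0.44
18,LilKyeburn Stream,River,78,42,375,0.23,0.44
19,North Col Stream,River,78,25,241,0.28,0.45
20,Coweeta (1),River,58,28,126,0.30,0.52
21,Martins Stream,River,105,48,343,0.32,0.51
22,Michigan Lake,Lake,33,5,127,0.37,0.48
23,Scotch Broom,Terrestrial,85,1,219,0.40,0.54
24,Grassland (U.K.),River,61,8,97,0.40,0.69
25,Ythan Estuary,Marine,82,5,391,0.42,0.50
26,Chesapeake Bay,Marine,31,5,67,0.45,0.62
27,Maspalomas Pond,Lake,18,8,24,0.49,1.01
28,Bridge Broom Lake,Lake,25,8,104,0.53,0.64
29,Florida Bay,Marine,121,14,1767,0.59,0.59
30,St. Martin Island,Terrestrial,42,6,205,0.59,0.63
31,Lough Hyne,Lake,349,49,5102,0.60,0.60
32,Skipwith Pond,Lake,25,1,189,0.61,0.54
33,Narragansett Bay,Marine,31,5,111,0.61,0.68
34,Cypress (Wet Season),Terrestrial,64,12,439,0.63,0.66
35,St. Marks Estuary,Marine,48,6,218,0.63,0.67
36,Carpinteria Salt Marsh Reserve,Marine,126,50,541,0.65,0.85
37,Little Rock Lake,Lake,92,12,984,0.67,0.65
38,Mangrove Estuary (Wet Season),Marine,90,6,1151,0.67,0.63
39,Benguela Current,Marine,29,2,196,0.69,0.65
40,Weddell Sea,Marine,483,61,15317,0.72,0.68
41,Caribbean (2005),Marine,249,5,3302,0.73,0.69
42,N.E. Shelf,Marine,79,2,1378,0.73,0.66
43,Caribbean Reef,Marine,50,3,535,0.94,0.82
44,El Verde Rainforest,Terrestrial,155,28,1507,1.01,0.99
45,Coachella Valley,Terrestrial,29,3,243,1.21,1.02
46,Everglades Graminoid Marshes,Terrestrial,64,4,681,1.35,1.10
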