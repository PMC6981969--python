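id,name,energy,sd
ZINC000001550477,Lapatinib,-10.07,0.67
ZINC000034638188,Pf-562271,-9.3,0.74
ZINC000063298074,Ilorasertib,-10.09,0.66
ZINC000034800096,Gw583373a,-11.02,1.01
ZINC000027184814,Vibriobactin,-9.77,0.74
ZINC000034800093,Gw580496a,-9.33,1.09
ZINC000150528975,Vedroprevir,-11.51,1.04
ZINC000034800112,Gw576484x,-10.36,0.84
ZINC000072190218,Avatrombopag,-9.28,0.43
ZINC000034800091,Gw576609a,-11.38,0.69
ZINC000044418656,Gw784684x,-10.77,0.93
ZINC000042804069,Gsk-182497a,-9.57,0.37
ZINC000103297739,Defactinib,-10.23,0.4
ZINC000004215255,Cefpimizole,-10.54,0.7
ZINC000042834127,Gsk1751853a,-10.34,1.4
ZINC000014945166,Gw830365a,-9.53,0.29
ZINC000150339466,Ciluprevir,-10.95,0.88
ZINC000043195317,Golvatinib,-14.0,1.06
ZINC000042201866,Gw566221a,-10.06,0.71
ZINC000095615094,Patellamide G,-9.32,0.79
ZINC000003604326,Vaneprim,-11.01,0.79
ZINC000002007399,Gw458787a,-10.95,0.76
ZINC000028639340,Posaconazole,-10.92,1.01
ZINC000072122048,Gsk259178a,-12.44,0.49
ZINC000068204830,Daclatasvir,-10.75,0.42
ZINC000043131420,Fostamatinib,-10.77,1.11
ZINC000169289453,Simeprevir,-11.45,0.88
ZINC000042834162,Gw869810x,-12.11,0.76
ZINC000049709569,Asperazine,-11.6,0.82
ZINC000096928979,Deleobuvir,-10.2,0.68
ZINC000042201868,Gw568377a,-9.36,0.6
ZINC000014945147,Gw809897x,-10.44,0.71
ZINC000014945171,Gw830263a,-10.53,0.57
ZINC000014945045,Gw569530a,-9.52,0.55
ZINC000003925087,Gw806742x,-10.43,0.78
ZINC000095618748,Candesartan O-Glucuronide,-9.71,0.58
ZINC000098052868,Olcegepant,-9.55,0.48
ZINC000049833405,Preulicyclamide,-11.13,0.62
ZINC000034800110,Gw574782a,-10.42,0.6
ZINC000014965596,Gw683134a,-10.91,0.8
ZINC000034800112,Gw576484x,-9.93,0.36
ZINC000019862646,Fedratinib,-10.23,0.64
ZINC000150377731,Bms-247243,-10.42,0.83
ZINC000003986669,Bx-795,-9.28,0.69
ZINC000095615898,Tyrokeradine A,-11.14,0.76
ZINC000003919988,L-766892,-9.59,0.67
ZINC000095544067,Ulithiacyclamide F,-9.76,0.52
ZINC000049889335,Edulirin A,-11.45,1.04
ZINC000003995140,Gw621823a,-10.63,0.63
ZINC000040379218,Gw684626b,-10.46,0.87
ZINC000034800121,Gw567808a,-10.42,0.53
ZINC000169306513,Hydroxyitraconazole,-9.78,1.02
ZINC000169368380,Kni-1039,-10.13,0.41
ZINC000150601177,Ombitasvir,-10.07,0.69
ZINC000040404350,Gsk-969786a,-10.2,0.75
ZINC000150592451,Micromide,-12.96,1.0
ZINC000028249631,Pd-170292,-10.1,0.73
ZINC000169366333,Porphyrin,-11.05,0.71
ZINC000034800119,Gw576924a,-10.18,0.92
ZINC000150362888,Pyropheophytin B,-10.23,0.73
ZINC000100057121,Tegobuvir,-10.55,0.58
ZINC000103213128,"Heptamethylene 1,7-Bis-Imadacloprid",-9.58,0.47
ZINC000169291993,Sansanmycin F,-9.5,0.56
ZINC000230052516,Urobilin,-10.9,0.85
ZINC000003994828,Brecanavir,-10.41,0.86
ZINC000169363931,Ansacarbamitocin C,-10.56,0.52
ZINC000095535868,Rwj-58259,-10.09,0.77
ZINC000003921862,Tallimustine,-9.76,0.67
ZINC000063933734,Rebastinib,-9.73,0.57
ZINC000095615652,Patellamide C,-9.46,0.73
ZINC000197688172,"S-[(3e,5z)-3,5-Octadienoate",-9.6,0.67
ZINC000014965588,Gw709042a,-9.89,0.89
ZINC000085537136,Barixibat,-9.72,0.56
ZINC000169291499,Kibdelomycin,-10.99,0.66
ZINC000003946578,Mitratapide,-10.41,0.62
ZINC000001481922,Setipafant,-10.05,0.62
ZINC000072173092,Deoxyvobstusine Lactone,-9.66,0.64
ZINC000006717126,Quarfloxin,-9.85,0.78
ZINC000077301904,Losartan N2-Glucuronide,-10.86,1.27
ZINC000150609364,Pseudoceratinazole A,-11.38,0.97
ZINC000095616246,Ulithiacyclamide E,-9.35,0.69
ZINC000068151111,Narlaprevir,-9.96,0.44
ZINC000150351429,Phytosulfokine B,-9.7,0.7
ZINC000003989268,Ceftaroline Fosamil,-9.84,0.62
ZINC000008552132,Stafac,-11.01,0.91
ZINC000095618880,Clofazimine Glucuronide,-9.65,0.58
ZINC000096006065,Xv638,-9.56,0.57
ZINC000169292535,Rifapentine,-12.81,0.92
ZINC000150341961,Mafodotin,-9.32,0.71
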