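species,previous_name,molecular,morphology,areas,elev_mean,elev_low,elev_high
Pteronymia alcmena,,,x,A,1100,1050,1200
Pteronymia aletta,,x,x,ABCE,693,50,1450
Pteronymia alicia,,,x,I,1235,1100,1490
Pteronymia alida,,x,x,CDE,1933,800,3000
Pteronymia andreas,alissa,x,x,CDI,1337,750,1860
Pteronymia alissa,,x,x,CE,1227,300,2000
Pteronymia artena,,x,x,ACDE,1365,900,2060
Pteronymia calgiria,,,x,D,1719,1300,2970
Pteronymia carlia,,x,x,H,910,100,1700
Pteronymia cotytto,,x,x,AE,776,80,1455
Pteronymia donella,,x,x,AB,386,20,825
Pteronymia euritea,,x,x,H,553,30,1250
Pteronymia forsteri,,x,x,F,632,182,1350
Pteronymia fulvimargo,,x,x,A,1455,1110,2060
Pteronymia fumida,,,x,AC,870,450,1000
Pteronymia gertschi,,x,x,C,950,500,1000
Pteronymia glauca,,,x,C,1230,800,1400
Pteronymia granica,,x,x,C,1929,1500,2250
Pteronymia hara,,x,x,ACDE,1474,600,2400
Pteronymia inania,,x,x,CE,1659,1200,2100
Pteronymia latilla,,x,x,ACE,1012,170,1925
Pteronymia laura,,x,x,CE,1088,800,1400
Pteronymia lonera,,x,x,A,1198,500,1575
Pteronymia medellina,,x,x,C,1707,1380,2000
Pteronymia obscuratus,,x,x,AB,257,30,700
Pteronymia olimba,,x,x,D,1403,1000,1525
Pteronymia oneida,,x,x,CE,1992,1250,2650
Pteronymia asopo,oneida,x,x,E,900,900,900
Pteronymia ozia,,x,x,CDE,1446,600,2500
Pteronymia parva,,x,x,A,842,200,2060
Pteronymia peteri,,,x,I,1040,1040,1040
Pteronymia picta,,x,x,ACE,1104,350,2060
Pteronymia dispar,picta,x,,C,1500,1300,1800
Pteronymia primula,,x,x,BFG,389,65,1050
Pteronymia rufocincta,,x,x,A,998,210,1500
Pteronymia sao,,x,x,FG,332,100,800
Pteronymia serrata,,x,x,CD,2091,1700,2300
Pteronymia sexpunctata,,x,x,D,1265,635,1500
Pteronymia simplex,,x,x,A,1544,1100,2300
Pteronymia tamina,,x,x,CD,1667,800,2075
Pteronymia thabena,teresita,x,x,CDE,1670,790,2400
Pteronymia teresita,,x,x,C,1184,1000,1350
Pteronymia ticida,,x,x,CDE,1784,1200,2400
Pteronymia tucuna,,x,x,F,777,100,1350
Pteronymia veia_EAST,veia,x,x,CE,1662,1000,2400
Pteronymia veia_WEST,veia,x,x,C,1729,1300,2150
Pteronymia vestilla,,x,x,F,398,100,900
Pteronymia alina,zerlina,x,x,CD,1784,700,2500
Pteronymia zerlina,,x,x,CE,1473,635,2000
Pteronymia spnov 1,,x,x,E,1730,1730,1730
Pteronymia spnov 2,,x,x,C,1765,850,2530
Pteronymia spnov 3,,x,x,C,1898,1700,2030
Pteronymia spnov 4,,x,x,A,656,500,700
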