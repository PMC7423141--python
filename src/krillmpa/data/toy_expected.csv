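year,season,variable,group,ssmu,value
0,initial,predators,penguins,1,20000.0
0,initial,predators,penguins,2,15000.0
0,initial,predators,seals,3,1200.0
0,summer,krill,,1,440327.79426855885
0,summer,catch,,1,9374.4
0,summer,krill,,2,590397.2315176004
0,summer,catch,,2,8035.2
0,summer,krill,,3,4231.895061756723
0,summer,catch,,3,20088.0
0,winter,krill,,1,292054.55235956114
0,winter,catch,,1,4017.6
0,winter,krill,,2,391665.6108733376
0,winter,catch,,2,5356.8
0,winter,krill,,3,0.0
0,winter,catch,,3,4125.111995369229
0,annual,predators,penguins,1,20000.0
0,annual,predators,penguins,2,15000.0
0,annual,predators,seals,3,1200.0
1,summer,krill,,1,435001.8014404462
1,summer,catch,,1,9374.4
1,summer,krill,,2,584810.5234145372
1,summer,catch,,2,8035.2
1,summer,krill,,3,0.0
1,summer,catch,,3,7020.5321782005785
1,winter,krill,,1,288484.4326018352
1,winter,catch,,1,4017.6
1,winter,krill,,2,387920.72844050464
1,winter,catch,,2,5356.8
1,winter,krill,,3,0.0
1,winter,catch,,3,0.0
1,annual,predators,penguins,1,19978.18251706305
1,annual,predators,penguins,2,14983.63688779729
1,annual,predators,seals,3,1183.404111861388
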