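scenario,group,ssmu_id,season,percent
D1MPA,whales,1,summer,56.9
D1MPA,whales,1,winter,36.8
D1MPA,fish,1,summer,3.4
D1MPA,fish,1,winter,3.4
D1MPA,penguins,2,summer,86.6
D1MPA,penguins,2,winter,55.7
D1MPA,fish,2,summer,30.7
D1MPA,fish,2,winter,30.7
D1MPA,penguins,3,summer,95.7
D1MPA,penguins,3,winter,35.9
D1MPA,seals,3,summer,53.6
D1MPA,seals,3,winter,8.5
D1MPA,fish,3,summer,50.3
D1MPA,fish,3,winter,50.3
D1MPA,penguins,4,summer,95.0
D1MPA,penguins,4,winter,27.8
D1MPA,seals,4,summer,53.6
D1MPA,seals,4,winter,8.5
D1MPA,fish,4,summer,33.5
D1MPA,fish,4,winter,33.5
D1MPA,penguins,5,summer,95.0
D1MPA,penguins,5,winter,28.7
D1MPA,fish,5,summer,64.7
D1MPA,fish,5,winter,64.7
D1MPA,penguins,6,summer,85.3
D1MPA,penguins,6,winter,53.6
D1MPA,fish,6,summer,42.0
D1MPA,fish,6,winter,42.0
D1MPA,penguins,7,summer,94.9
D1MPA,penguins,7,winter,27.0
D1MPA,seals,7,summer,53.6
D1MPA,seals,7,winter,8.5
D1MPA,fish,7,summer,35.0
D1MPA,fish,7,winter,35.0
D1MPA,penguins,8,summer,76.7
D1MPA,penguins,8,winter,59.3
D1MPA,fish,8,summer,17.0
D1MPA,fish,8,winter,17.0
D1MPA,whales,9,summer,5.5
D1MPA,whales,9,winter,0.0
D1MPA,fish,9,summer,11.5
D1MPA,fish,9,winter,11.5
D1MPA,penguins,10,summer,94.8
D1MPA,penguins,10,winter,8.0
D1MPA,fish,10,summer,11.0
D1MPA,fish,10,winter,11.0
D1MPA,penguins,11,summer,77.0
D1MPA,penguins,11,winter,3.3
D1MPA,fish,11,summer,31.6
D1MPA,fish,11,winter,31.6
D1MPA,penguins,12,summer,90.3
D1MPA,penguins,12,winter,7.3
D1MPA,fish,12,summer,28.8
D1MPA,fish,12,winter,28.8
US10,whales,1,summer,82.4
US10,whales,1,winter,56.7
US10,fish,1,summer,14.3
US10,fish,1,winter,14.3
US10,penguins,2,summer,28.0
US10,penguins,2,winter,46.1
US10,fish,2,summer,60.7
US10,fish,2,winter,60.7
US10,penguins,3,summer,49.4
US10,penguins,3,winter,31.5
US10,seals,3,summer,65.5
US10,seals,3,winter,10.9
US10,fish,3,summer,43.9
US10,fish,3,winter,43.9
US10,penguins,4,summer,49.3
US10,penguins,4,winter,22.9
US10,seals,4,summer,65.5
US10,seals,4,winter,10.9
US10,fish,4,summer,59.1
US10,fish,4,winter,59.1
US10,penguins,5,summer,49.3
US10,penguins,5,winter,23.9
US10,fish,5,summer,75.3
US10,fish,5,winter,75.3
US10,penguins,6,summer,25.7
US10,penguins,6,winter,43.2
US10,fish,6,summer,22.4
US10,fish,6,winter,22.4
US10,penguins,7,summer,0.0
US10,penguins,7,winter,22.0
US10,seals,7,summer,0.0
US10,seals,7,winter,10.9
US10,fish,7,summer,0.0
US10,fish,7,winter,0.0
US10,penguins,8,summer,7.7
US10,penguins,8,winter,42.7
US10,fish,8,summer,0.8
US10,fish,8,winter,0.8
US10,whales,9,summer,50.0
US10,whales,9,winter,0.0
US10,fish,9,summer,11.5
US10,fish,9,winter,11.5
US10,penguins,10,summer,0.0
US10,penguins,10,winter,9.4
US10,fish,10,summer,0.0
US10,fish,10,winter,0.0
US10,penguins,11,summer,0.0
US10,penguins,11,winter,0.1
US10,fish,11,summer,0.0
US10,fish,11,winter,0.0
US10,penguins,12,summer,0.0
US10,penguins,12,winter,7.3
US10,fish,12,summer,0.0
US10,fish,12,winter,0.0
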