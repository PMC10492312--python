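sex,age_min,age_max,risk_label,bf_min,bf_max
female,18,29,excellent,0,16
female,18,29,good,16,20
female,18,29,normal,20,25
female,18,29,overfat,25,32
female,18,29,obese,32,100
female,30,39,excellent,0,17
female,30,39,good,17,21
female,30,39,normal,21,26
female,30,39,overfat,26,33
female,30,39,obese,33,100
female,40,49,excellent,0,18
female,40,49,good,18,23
female,40,49,normal,23,28
female,40,49,overfat,28,34
female,40,49,obese,34,100
female,50,59,excellent,0,19
female,50,59,good,19,25
female,50,59,normal,25,30
female,50,59,overfat,30,35
female,50,59,obese,35,100
female,60,79,excellent,0,20
female,60,79,good,20,26
female,60,79,normal,26,31
female,60,79,overfat,31,36
female,60,79,obese,36,100
male,18,29,excellent,0,11
male,18,29,good,11,14
male,18,29,normal,14,18
male,18,29,overfat,18,25
male,18,29,obese,25,100
male,30,39,excellent,0,12
male,30,39,good,12,16
male,30,39,normal,16,20
male,30,39,overfat,20,26
male,30,39,obese,26,100
male,40,49,excellent,0,14
male,40,49,good,14,18
male,40,49,normal,18,22
male,40,49,overfat,22,27
male,40,49,obese,27,100
male,50,59,excellent,0,15
male,50,59,good,15,19
male,50,59,normal,19,23
male,50,59,overfat,23,28
male,50,59,obese,28,100
male,60,79,excellent,0,16
male,60,79,good,16,20
male,60,79,normal,20,24
male,60,79,overfat,24,29
male,60,79,obese,29,100
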