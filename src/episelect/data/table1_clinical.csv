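patient_id,age,sex,side,onset_age,duration,seizure_type,seizure_freq,engel,followup_years,behavioral_testing
H48,41,m,L,18,23,gen,weekly,I,12,NA
H57,27,m,R,13,14,PC,3 weekly,I,11,NA
H61,17,f,R,7,17,PC,2 weekly,I,11,NA
H67,39,m,R,1,38,gen,weekly,I,11,NA
H75,37,m,L,13,24,PC,2 weekly,II,10,NA
H84,31,m,R,2,29,gen,4 weekly,I,10,NA
H94,27,m,L,20,7,gen,3-5 weekly,II,9,NA
H104,32,m,L,12,20,PC,weekly,I,9,NA
H108,50,m,L,15,35,gen,4 weekly,III,9,NA
H109,22,f,R,4,18,PC,0-3 weekly,I,9,NA
H115,40,f,L,1.8,38,gen,4 weekly,III,9,NA
H123,24,f,L,7,17,gen,daily,I,8,NA
H136,20,f,R,0.7,19,gen,weekly,I,8,NA
H220,53,f,L,13,40,PC,weekly,I,4,NA
H225,49,f,R,16,33,PC,weekly,I,4,NA
H229,40,f,R,2,38,PC,weekly,I,4,NA
H230,22,f,L,18,4,"PC, gen",daily,III,3,NA
H231,23,m,L,1,22,"PC, gen",daily,I,3,NA
H233,35,m,L,6,29,"PC, gen",weekly,III,3,NA
H236,54,f,R,16,38,"PC, gen",weekly,I,3,NA
H237,41,f,L,20,21,"PC, gen",2 weekly,I,3,NA
H238,22,f,R,11,11,PC,weekly,I,3,NA
H241,43,f,L,4,39,"PC, gen",Not regular,I,3,NA
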