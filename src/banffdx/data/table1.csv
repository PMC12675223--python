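record_id,patient_id,bx_year,bx_type,day_after_tx,abo,hla_dsa,t,t_ifta,i,i_ifta,v,g,ptc,c4d,cg,cv,ci,ct,ptcbm,tma,pathologist_dx,expected_engine_dx,known_deviation
T1-104347-2018-d359,104347,2018,protocol,359,compatible,-,0,,0,,1,0,1,2,0,1,,,1,false,CA-AMR,A-TCMR,false
T1-104461-2018-d347,104461,2018,protocol,347,incompatible,-,0,,0,,0,1,0,0,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-104529-2019-d359,104529,2019,protocol,359,incompatible,-,0,,0,,0,1,0,2,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-104601-2019-d365,104601,2019,protocol,365,compatible,-,1,,0,,0,0,2,1,0,0,1,1,0,false,A-AMR,IFTA,true
T1-104797-2019-d58,104797,2019,follow_up,58,incompatible,-,0,,0,,0,0,1,2,2,3,1,1,0,false,CA-AMR,IFTA,false
T1-104797-2019-d24,104797,2019,follow_up,24,incompatible,-,0,,0,,0,0,1,0,0,3,,,0,false,A-AMR,NO-REJECTION,false
T1-104949-2020-d12,104949,2020,for_cause,12,incompatible,-,1,,0,,0,0,1,2,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-105058-2021-d105,105058,2021,protocol,105,incompatible,-,0,,0,,0,1,0,2,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-105139-2021-d97,105139,2021,protocol,97,incompatible,-,0,,0,,0,0,2,1,0,0,1,1,0,false,A-AMR,IFTA,false
T1-105178-2022-d115,105178,2022,protocol,115,compatible,+,0,,0,,0,1,0,1,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-105182-2022-d100,105182,2022,protocol,100,incompatible,-,0,,0,,0,0,1,3,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-105190-2022-d89,105190,2022,protocol,89,incompatible,-,0,,0,,0,1,0,3,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-105194-2022-d108,105194,2022,protocol,108,compatible,-,0,,0,,0,1,0,1,0,0,,,0,false,CA-AMR,NO-REJECTION,false
T1-105237-2022-d6,105237,2022,for_cause,6,compatible,+,0,,1,,0,1,0,0,0,0,,,0,false,A-AMR,NO-REJECTION,false
T1-104309-2017-d113,104309,2017,for_cause,113,compatible,-,2,,0,,0,1,1,0,0,0,,,0,false,BC,A-AMR,false
T1-104431-2017-d1092,104431,2017,for_cause,1092,incompatible,-,0,,0,,0,1,1,2,0,0,,,0,false,PGNMID recurrence,A-AMR,false
T1-104488-2018-d870,104488,2018,for_cause,870,compatible,-,3,,0,,0,0,2,0,0,0,,,0,false,FSGS recurrence,A-AMR,false
T1-104553-2018-d380,104553,2018,protocol,380,compatible,-,0,,0,,0,1,0,2,0,0,,,0,false,No rejection,A-AMR,false
T1-104580-2018-d86,104580,2018,protocol,86,compatible,+,0,,0,,0,0,2,0,0,0,,,0,false,No rejection,A-AMR,false
T1-104580-2018-d16,104580,2018,for_cause,16,compatible,+,0,,0,,0,0,2,1,0,0,,,0,false,Toxic tubulopathy,A-AMR,false
T1-104805-2019-d1083,104805,2019,for_cause,1083,compatible,-,1,,0,,0,0,2,2,0,0,,,1,false,CA-TCMR,A-AMR,false
T1-104888-2019-d677,104888,2019,for_cause,677,compatible,-,0,,0,,0,1,2,0,0,0,,,0,false,BKV nephropathy,A-AMR,false
T1-104925-2020-d28,104925,2020,for_cause,28,compatible,-,2,,0,,0,0,2,0,0,0,,,0,false,IF/TA,A-AMR,false
T1-105064-2021-d497,105064,2021,protocol,497,compatible,-,0,,0,,0,0,2,0,0,0,,,0,false,No rejection,CA-AMR,true
T1-105128-2021-d23,105128,2021,follow_up,23,incompatible,+,0,,0,,0,2,0,2,1,0,,,0,true,TMA,CA-AMR,false
T1-105149-2021-d21,105149,2021,for_cause,21,compatible,-,0,,0,,0,2,1,2,0,0,,,0,false,FSGS recurrence,A-AMR,false
T1-105181-2021-d50,105181,2021,for_cause,50,compatible,-,1,,1,,0,2,2,1,0,0,,,0,false,A-TCMR 1A,A-AMR,false
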