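record_id,patient_id,bx_year,bx_type,day_after_tx,abo,hla_dsa,t,t_ifta,i,i_ifta,v,g,ptc,c4d,cg,cv,ci,ct,ptcbm,tma,pathologist_dx,expected_engine_dx,known_deviation
T2-104805-2022-d1083,104805,2022,protocol,1083,compatible,-,1,3,0,2,0,0,2,2,0,0,3,3,,false,CA-TCMR,A-AMR,false
T2-104429-2018-d361,104429,2018,for_cause,361,compatible,-,0,–,0,1,0,0,0,0,0,0,0,0,,false,A-TCMR,NO-REJECTION,false
T2-104441-2021-d1435,104441,2021,protocol,1435,incompatible,-,0,0,1,3,0,0,2,0,0,0,3,3,,false,CA-TCMR,IFTA,false
T2-104597-2019-d178,104597,2019,follow_up,178,compatible,-,2,–,1,1,0,0,1,1,0,0,1,1,,false,A-TCMR,BC,false
T2-104888-2021-d677,104888,2021,for_cause,677,compatible,-,0,3,0,2,0,1,2,0,0,0,3,3,,false,CA-TCMR,A-AMR,false
T2-104962-2021-d431,104962,2021,protocol,431,compatible,-,0,1,0,1,0,0,0,0,0,0,1,1,,false,CA-TCMR,IFTA,false
T2-104971-2020-d88,104971,2020,protocol,88,incompatible,-,0,3,0,2,0,0,2,3,0,0,1,1,,false,CA-TCMR,IFTA,false
T2-105181-2022-d50,105181,2022,protocol,50,compatible,-,1,0,1,1,0,2,2,1,0,0,2,2,,false,A-TCMR,A-AMR,false
T2-105165-2022-d97,105165,2022,protocol,97,compatible,-,2,0,0,3,0,0,2,0,0,0,0,0,,false,BC,CA-TCMR,false
T2-105168-2022-d176,105168,2022,protocol,176,compatible,-,2,1,1,2,0,0,2,0,0,0,2,2,,false,BC,CA-TCMR,false
T2-104347-2018-d359,104347,2018,protocol,359,compatible,-,0,–,0,–,1,0,0,1,0,1,0,0,,false,CA-AMR,A-TCMR,false
T2-104420-2019-d649,104420,2019,for_cause,649,compatible,-,2,–,0,2,0,0,2,0,0,0,0,0,,false,No rejection,CA-TCMR,false
T2-104661-2019-d373,104661,2019,protocol,373,compatible,-,2,–,1,2,0,0,0,0,0,0,1,1,,false,No rejection,CA-TCMR,false
T2-104336-2018-d365,104336,2018,for_cause,365,compatible,-,3,–,0,2,0,0,2,0,0,0,2,2,,false,No rejection,CA-TCMR,false
T2-104851-2020-d256,104851,2020,for_cause,256,compatible,-,0,3,0,2,0,0,2,0,0,0,2,2,,false,No rejection,CA-TCMR,false
T2-105052-2021-d206,105052,2021,for_cause,206,compatible,-,3,0,1,2,0,0,2,1,0,0,2,2,,false,No rejection,CA-TCMR,false
T2-104395-2017-d114,104395,2017,protocol,114,compatible,-,1,–,0,–,1,0,1,3,0,–,0,0,,false,No rejection,A-TCMR,false
T2-104396-2017-d85,104396,2017,protocol,85,compatible,-,2,–,2,–,0,0,2,1,0,–,1,1,,false,No rejection,A-TCMR,false
T2-104866-2020-d368,104866,2020,protocol,368,compatible,-,0,0,0,0,1,0,1,0,0,0,1,1,,false,No rejection,A-TCMR,false
T2-104347-2017-d109,104347,2017,protocol,109,compatible,-,0,–,0,–,1,0,0,1,0,1,0,0,,false,Other,A-TCMR,false
T2-105060-2021-d360,105060,2021,protocol,360,compatible,-,0,0,0,0,2,1,0,0,0,0,0,0,,false,Other,A-TCMR,false
T2-105192-2022-d16,105192,2022,for_cause,16,incompatible,-,0,–,1,0,3,1,0,2,0,0,0,0,,true,TMA,A-TCMR,false
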