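patient_id,index_date,age,sex,ethnicity,bmi,waist_circumference,sbp,dbp,egfr,acr,hba1c,phosphorus,fgf23,diabetes_duration,smoking,hypertension,cvd,medication_compliance,followup_months,event,censor_reason
P001,2019-03,62,female,saudi,31.5,104,141,79,95.2,14,8.4,3.6,52.1,12,never,true,false,9,48,false,administrative
P002,2019-07,55,male,saudi,29.8,101,128,82,71.4,38,7.2,3.9,61.0,8,current,false,false,7,21,true,none
P003,2020-01,71,female,saudi,34.1,,152,75,48.9,112,,4.2,88.4,19,former,true,true,6,36,false,administrative
P004,2020-06,47,male,non_saudi,27.3,96,124,70,102.6,6,6.8,3.4,41.7,3,never,false,false,10,44,false,administrative
P005,2021-02,64,female,saudi,36.9,118,149,88,33.5,260,9.1,4.5,120.3,22,never,true,false,5,9,false,death
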