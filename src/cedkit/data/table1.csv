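subject,sex,age_years,total_ced_treatments,dose_level,dlt,followup_months,status
S1,F,7.5,1,1,No,13.7,death
S2,M,40.2,2,2,No,65.4,alive
S3,M,13.1,2,2-1,Yes,9.1,lost
S4,F,7.2,5,2,No,19.3,death
S5,F,5.5,2,2,No,11.2,death
S6,F,31.5,1,2,No,14.3,death
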