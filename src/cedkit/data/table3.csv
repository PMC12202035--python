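subject,ced_number,gad_mM,vi_mL,duration_min,tumor_cm3,vd_cm3,total_vd_cm3,covered_cm3,coverage_pct
S1,1,2.0,2,236,45.1,7.6,7.6,7.5,16.6
S2,1,2.0,3,416,23.9,9.8,12.2,10.3,42.9
S2,2,2.0,3,350,,7.2,,,
S3,1,2.0,3,335,26.7,7.9,11.2,10.6,39.7
S3,2,1.0,2,244,,5.8,,,
S4,1,0.5,3,419,21.1,5.0,16.4,13.5,63.7
S4,2,0.5,3,359,,6.4,,,
S4,3,0.5,3,344,,6.9,,,
S4,4,0.5,3,460,,5.5,,,
S4,5,0.1,3,377,,0.7,,,
S5,1,0.5,3,417,32.4,7.0,11.7,10.1,31.3
S5,2,0.5,3,387,,5.4,,,
S6,1,0.5,3,357,24.4,5.6,5.6,4.4,17.9
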