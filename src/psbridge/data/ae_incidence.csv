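preferred_term,pali_n,pali_pct,placebo_pali_n,placebo_pali_pct,ris_2_4_n,ris_2_4_pct,ris_4_6_n,ris_4_6_pct,placebo_ris_n,placebo_ris_pct,printed_diff_vs_2_4,printed_diff_vs_4_6
insomnia,26,14.5,9,9.5,25,22.1,22,17.1,23,18.9,,5.0
sinus tachycardia,14,7.8,4,4.2,1,0.9,2,1.6,0,0.0,2.7,2.0
tachycardia,12,6.7,3,3.2,1,0.9,3,2.3,0,0.0,2.6,
somnolence,7,3.9,5,5.3,10,8.9,9,7.0,2,1.6,7.3,5.4
restlessness,0,0.0,0,0.0,9,8.0,7,5.4,1,0.8,7.2,4.6
nausea,4,2.2,4,4.2,9,8.0,11,8.5,4,3.3,4.7,5.2
anxiety,3,1.7,2,2.1,11,9.7,14,10.9,7,5.7,4.0,5.2
salivary hypersecretion,3,1.7,0,0.0,6,5.3,5,3.9,0,0.0,3.6,2.2
akathisia,8,4.5,3,3.2,5,4.4,6,4.7,1,0.8,2.3,2.6
dizziness,8,4.5,3,3.2,5,4.4,8,6.2,3,2.5,,2.4
nasal congestion,1,0.6,0,0.0,4,3.5,7,5.4,3,2.5,,2.3
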