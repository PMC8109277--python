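country,ind1_score,ind2_score,ind3_score,ind4_score,ind5_score,ind6_score,ind7_score,ind8_score,ind9_score,expenditure_per_capita_usd
Switzerland,3,3,3,3,3,2,3,1,3,9956.3
France,3,3,3,3,2,2,3,3,3,4379.9
Germany,2,3,3,3,3,2,2,1,3,5033.5
Japan,3,3,3,3,3,2,2,2,2,4169.0
Singapore,3,3,2,3,2,1,2,3,1,2618.7
UK,2,2,3,2,3,2,1,2,2,3858.7
USA,2,2,3,2,3,2,2,1,1,10246.1
Russia,2,2,3,2,2,1,1,2,1,585.9
China,2,3,2,2,1,1,1,2,2,440.8
Brazil,2,2,3,2,1,1,1,1,1,928.8
India,1,2,1,1,1,1,1,1,1,69.3
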