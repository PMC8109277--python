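country,indicator_id,adopted_score,agreement_pct
France,8,3,71.4
France,9,3,71.4
Germany,7,2,71.4
Germany,9,3,71.4
Japan,3,3,57.1
Japan,7,2,85.7
Japan,8,2,71.4
Japan,9,2,71.4
Singapore,3,2,57.1
Singapore,7,2,57.1
UK,7,1,57.1
UK,8,2,57.1
USA,7,2,85.7
USA,8,1,100.0
USA,9,1,57.1
Russia,6,1,71.4
Russia,7,1,71.4
Russia,8,2,57.1
China,6,1,71.4
China,7,1,71.4
China,8,2,57.1
China,9,2,57.1
Brazil,6,1,71.4
Brazil,7,1,71.4
Brazil,8,1,85.7
Brazil,9,1,85.7
India,3,1,85.7
India,6,1,85.7
India,7,1,85.7
India,8,1,100.0
India,9,1,85.7
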