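stratum_kind,stratum_id,positivity_pct,potential_reach
age_band,13-19,1.50,890000
age_band,20-29,2.10,5400000
age_band,30-39,1.90,3800000
age_band,40-49,1.30,2200000
age_band,50+,0.80,3200000
region,Northeast,1.30,2700000
region,Midwest,1.60,2900000
region,South,2.30,6200000
region,West,1.20,3800000
region,US dependent areas,1.10,150000
national,Total,1.70,16000000
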