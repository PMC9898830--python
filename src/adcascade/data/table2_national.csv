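state,potential_reach,budget_low,budget_high,reach_ll,reach_hl,reach_lh,reach_hh,clicks_ll,clicks_hl,clicks_lh,clicks_hh
All United States,3300000,17480,104590,114200,330000,330000,953600,3700,10700,9300,27000
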