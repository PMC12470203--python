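site_id,cd_total_mg_kg,cd_avail_ug_kg,se_total_mg_kg,se_avail_ug_kg,ph,som_g_kg,tn_g_kg,tp_g_kg,ap_mg_kg,ak_mg_kg
no.1,0.34,87.21,2.26,62.50,,,,,,
no.2,0.44,111.75,2.19,53.10,,,,,,
no.3,0.48,98.32,2.58,31.27,,,,,,
no.4,0.18,46.56,1.76,58.87,,,,,,
no.5,0.20,47.84,2.93,99.20,,,,,,
no.6,0.54,96.54,2.04,34.57,,,,,,
no.7,0.40,25.19,3.16,44.03,,,,,,
no.8,0.48,29.77,1.46,22.30,,,,,,
no.9,0.23,81.34,3.99,75.00,,,,,,
no.10,0.55,110.84,5.50,78.07,,,,,,
no.11,0.47,61.85,1.49,18.53,,,,,,
no.12,0.18,53.55,1.54,65.27,,,,,,
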