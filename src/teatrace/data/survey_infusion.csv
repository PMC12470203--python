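site_id,element,conc_ug_L,tea_mass_kg,water_volume_L
no.1,Cd,0.163,0.005,0.100
no.2,Cd,0.148,0.005,0.100
no.3,Cd,0.175,0.005,0.100
no.4,Cd,0.131,0.005,0.100
no.5,Cd,0.130,0.005,0.100
no.6,Cd,0.138,0.005,0.100
no.7,Cd,0.147,0.005,0.100
no.8,Cd,0.127,0.005,0.100
no.9,Cd,0.138,0.005,0.100
no.10,Cd,0.148,0.005,0.100
no.11,Cd,0.134,0.005,0.100
no.12,Cd,0.116,0.005,0.100
no.1,Se,7.06,0.005,0.100
no.2,Se,2.31,0.005,0.100
no.3,Se,2.42,0.005,0.100
no.4,Se,1.93,0.005,0.100
no.5,Se,2.81,0.005,0.100
no.6,Se,11.17,0.005,0.100
no.7,Se,12.29,0.005,0.100
no.8,Se,3.31,0.005,0.100
no.9,Se,8.46,0.005,0.100
no.10,Se,4.14,0.005,0.100
no.11,Se,3.49,0.005,0.100
no.12,Se,2.79,0.005,0.100
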