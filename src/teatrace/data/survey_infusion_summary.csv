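site_id,cd_inf_mean,cd_inf_sd,cd_leach_mean,cd_leach_sd,se_inf_mean,se_inf_sd,se_leach_mean,se_leach_sd,risk_measured,risk_total,n
no.1,0.163,0.019,11.34,1.89,7.06,0.04,25.66,1.49,2.95e-8,2.60e-7,3
no.2,0.148,0.006,9.70,1.47,2.31,0.10,17.47,2.05,2.53e-8,2.61e-7,3
no.3,0.175,0.022,13.56,2.13,2.42,0.06,21.55,0.90,3.29e-8,2.43e-7,3
no.4,0.131,0.005,18.39,0.78,1.93,0.04,12.25,1.34,3.30e-8,1.79e-7,3
no.5,0.130,0.007,10.99,0.97,2.81,0.13,21.99,2.33,3.27e-8,2.97e-7,3
no.6,0.138,0.007,6.98,0.82,11.17,1.06,14.18,1.03,3.51e-8,5.03e-7,3
no.7,0.147,0.002,12.14,0.51,12.29,0.19,22.78,0.95,3.84e-8,3.16e-7,3
no.8,0.127,0.021,11.60,2.13,3.31,0.13,35.56,16.05,3.39e-8,2.92e-7,3
no.9,0.138,0.008,15.15,1.36,8.46,0.36,20.69,1.17,3.50e-8,2.31e-7,3
no.10,0.148,0.004,12.71,0.35,4.14,0.11,28.94,1.49,3.79e-8,2.98e-7,3
no.11,0.134,0.001,19.35,0.83,3.49,0.01,18.93,0.74,3.38e-8,1.75e-7,3
no.12,0.116,0.007,18.05,1.87,2.79,0.16,31.39,2.94,2.88e-8,1.60e-7,3
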