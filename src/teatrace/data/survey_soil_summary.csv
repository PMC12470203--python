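site_id,cd_mean,cd_sd,acd_mean,acd_sd,arcd_mean,arcd_sd,se_mean,se_sd,ase_mean,ase_sd,arse_mean,arse_sd,pi_mean,pi_sd,n
no.1,0.34,0.01,87.21,16.10,25.82,4.43,2.26,0.39,62.50,42.25,2.62,1.38,1.12,0.03,3
no.2,0.44,0.03,111.75,8.08,25.67,0.30,2.19,0.44,53.10,26.72,2.44,1.07,1.45,0.11,3
no.3,0.48,0.03,98.32,9.76,20.59,3.60,2.58,1.07,31.27,17.26,1.48,1.01,1.60,0.11,3
no.4,0.18,0.01,46.56,1.12,25.86,1.44,1.76,0.02,58.87,16.85,3.36,0.99,0.60,0.03,3
no.5,0.20,0.01,47.84,3.57,24.41,1.50,2.93,0.93,99.20,40.50,3.33,0.68,0.65,0.02,3
no.6,0.54,0.30,96.54,93.01,15.66,7.26,2.04,1.12,34.57,21.16,2.08,1.76,1.81,0.99,3
no.7,0.40,0.10,25.19,10.23,6.69,3.15,3.16,1.02,44.03,22.86,1.55,0.98,1.33,0.34,3
no.8,0.48,0.09,29.77,2.35,6.44,1.74,1.46,0.37,22.30,14.39,1.43,0.58,1.59,0.32,3
no.9,0.23,0.03,81.34,2.62,36.22,3.15,3.99,1.12,75.00,6.10,1.99,0.62,0.75,0.09,3
no.10,0.55,0.04,110.84,6.76,20.11,2.36,5.50,1.10,78.07,16.14,1.43,0.19,1.85,0.14,3
no.11,0.47,0.05,61.85,26.94,13.07,4.88,1.49,0.38,18.53,5.76,1.31,0.60,1.56,0.17,3
no.12,0.18,0.02,53.55,4.77,30.60,4.81,1.54,0.07,65.27,7.09,4.25,0.65,0.59,0.08,3
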