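po4_level,fe_level,mu_optimal_no3,sr_mu_optimal_no3,tg_optimal_no3,mu_low_no3,sr_mu_low_no3,tg_low_no3,mu_extreme_no3,sr_mu_extreme_no3,tg_extreme_no3,mu_n2_only,sr_mu_n2_only,tg_n2_only
low,low,0.31,0.06,2.33,0.19,0.01,3.74,0.05,0.00,12.91,0.30,0.03,2.32
low,medium,0.31,0.06,2.36,0.13,0.02,5.29,,,,0.26,0.06,2.81
low,high,0.35,0.08,2.08,0.13,0.01,5.56,0.03,0.00,20.87,0.43,0.26,2.53
medium,low,0.33,0.09,2.24,0.25,0.03,2.82,,,,0.42,0.12,1.79
medium,medium,0.27,0.01,2.60,0.29,0.05,2.49,,,,0.22,0.04,3.28
medium,high,0.42,0.00,1.63,0.20,0.03,3.47,,,,0.25,0.10,3.25
high,low,0.28,0.05,2.56,0.40,0.02,1.75,0.07,0.02,10.84,0.45,0.23,2.06
high,medium,0.35,0.04,2.04,0.39,0.01,1.77,,,,0.50,0.09,1.44
high,high,0.34,0.03,2.04,0.20,0.03,3.54,0.03,0.01,21.36,0.74,0.00,0.94
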