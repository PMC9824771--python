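case_id,mu_right,mu_left,sigma_right,sigma_left,f1,f2,f3,label,affected_side
IBC_1,0.06,0.10,0.05,0.11,0.55,0.48,0.48,IBC,left
IBC_2,0.36,0.43,0.12,0.12,0.83,1.03,2.51,IBC,right
IBC_3,0.24,0.40,0.09,0.14,0.61,0.67,0.30,IBC,left
IBC_4,0.06,0.12,0.06,0.13,0.50,0.49,0.38,IBC,left
IBC_5,0.36,0.17,0.10,0.09,2.14,1.16,1.78,IBC,right
IBC_6,0.22,0.08,0.16,0.08,2.61,1.95,1.10,IBC,right
NON-IBC_1,0.28,0.25,0.06,0.06,1.18,1.05,0.95,non-IBC,
NON-IBC_2,0.17,0.15,0.12,0.11,1.12,1.14,0.62,non-IBC,
NON-IBC_3,0.14,0.14,0.07,0.05,1.01,1.46,0.73,non-IBC,
NON-IBC_4,0.07,0.11,0.05,0.08,0.62,0.61,0.94,non-IBC,
NON-IBC_5,0.28,0.26,0.11,0.07,1.10,1.50,0.71,non-IBC,
NON-IBC_6,0.14,0.12,0.12,0.09,1.15,1.40,0.75,non-IBC,
NON-IBC_7,0.23,0.27,0.08,0.08,0.88,0.92,1.61,non-IBC,
NON-IBC_8,0.06,0.09,0.06,0.08,0.65,0.70,1.17,non-IBC,
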