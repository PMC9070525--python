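class_name,n_trialled,ate_median,ate_q1,ate_q3,cate_median,cate_q1,cate_q3,overall_true,conditional_true,cv_accuracy,cv_sd
botulinum_toxin,111,0.44,0.33,0.56,0.56,0.48,0.65,0.47,0.51,0.53,0.03
flunarizine,42,0.31,0.23,0.42,0.42,0.35,0.49,0.64,0.76,0.64,0.11
candesartan,25,0.27,0.15,0.41,0.42,0.36,0.47,0.16,0.17,0.87,0.16
tca,185,0.22,0.14,0.32,0.32,0.25,0.41,0.31,0.35,0.69,0.02
valproate,68,0.17,0.14,0.32,0.29,0.20,0.36,0.26,0.32,0.74,0.05
topiramate,121,0.16,0.10,0.27,0.27,0.20,0.33,0.29,0.28,0.71,0.04
snri,66,0.16,0.13,0.22,0.22,0.20,0.30,0.29,0.33,0.71,0.05
acupuncture,74,0.13,0.10,0.19,0.19,0.16,0.28,0.28,0.24,0.72,0.03
betablockers,146,0.11,0.06,0.18,0.18,0.14,0.34,0.14,0.16,0.86,0.02
serotonergic,55,0.06,0.04,0.09,0.09,0.08,0.11,0.16,0.22,0.84,0.06
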