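factor,code,label,rr
abortions,0,0,1.0
abortions,1,1-2,2.512
abortions,2,>=3,6.313
age_first_live_birth,0,<25,1.0
age_first_live_birth,1,25-29,1.895
age_first_live_birth,2,>=30,3.589
benign_breast_disease,0,no,1.0
benign_breast_disease,1,yes,4.255
bmi,0,<24,1.0
bmi,1,24-27.9,1.372
bmi,2,>=28,1.882
family_history,0,no,1.0
family_history,1,yes,3.250
life_satisfaction,0,<13,1.0
life_satisfaction,1,>=13,2.424
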