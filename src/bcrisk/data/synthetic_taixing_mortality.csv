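age_start,age_end,rate_per_100k
25,29,40
30,34,50
35,39,70
40,44,110
45,49,170
50,54,270
55,59,430
60,64,700
65,69,1200
70,74,2100
75,79,3800
80,84,7000
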