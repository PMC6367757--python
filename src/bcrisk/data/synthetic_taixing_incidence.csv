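age_start,age_end,rate_per_100k
25,29,6
30,34,12
35,39,24
40,44,40
45,49,56
50,54,62
55,59,56
60,64,50
65,69,44
70,74,36
75,79,28
80,84,22
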