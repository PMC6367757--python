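age,duration,rr,risk_pct
25,10,1,0.01
25,10,5,0.03
25,10,10,0.06
25,10,15,0.09
25,10,20,0.12
25,10,25,0.15
25,20,1,0.07
25,20,5,0.36
25,20,10,0.71
25,20,15,1.06
25,20,20,1.42
25,20,25,1.77
25,30,1,0.18
25,30,5,0.88
25,30,10,1.74
25,30,15,2.60
25,30,20,3.46
25,30,25,4.30
30,5,1,0.01
30,5,5,0.03
30,5,10,0.06
30,5,15,0.09
30,5,20,0.12
30,5,25,0.15
30,10,1,0.01
30,10,5,0.06
30,10,10,0.11
30,10,15,0.17
30,10,20,0.22
30,10,25,0.28
30,20,1,0.14
30,20,5,0.69
30,20,10,1.37
30,20,15,2.04
30,20,20,2.71
30,20,25,3.38
30,30,1,0.22
30,30,5,1.09
30,30,10,2.16
30,30,15,3.22
30,30,20,4.27
30,30,25,5.31
40,5,1,0.06
40,5,5,0.30
40,5,10,0.60
40,5,15,0.91
40,5,20,1.20
40,5,25,1.50
40,10,1,0.13
40,10,5,0.63
40,10,10,1.26
40,10,15,1.89
40,10,20,2.51
40,10,25,3.13
40,20,1,0.21
40,20,5,1.04
40,20,10,2.06
40,20,15,3.08
40,20,20,4.08
40,20,25,5.08
40,30,1,0.28
40,30,5,1.39
40,30,10,2.76
40,30,15,4.10
40,30,20,5.43
40,30,25,6.74
50,5,1,0.04
50,5,5,0.20
50,5,10,0.40
50,5,15,0.60
50,5,20,0.80
50,5,25,0.99
50,10,1,0.08
50,10,5,0.42
50,10,10,0.83
50,10,15,1.24
50,10,20,1.65
50,10,25,2.06
50,20,1,0.16
50,20,5,0.78
50,20,10,1.55
50,20,15,2.31
50,20,20,3.07
50,20,25,3.82
50,30,1,0.20
50,30,5,1.01
50,30,10,2.01
50,30,15,3.00
50,30,20,3.99
50,30,25,4.96
60,5,1,0.04
60,5,5,0.20
60,5,10,0.41
60,5,15,0.61
60,5,20,0.81
60,5,25,1.01
60,10,1,0.08
60,10,5,0.38
60,10,10,0.76
60,10,15,1.13
60,10,20,1.51
60,10,25,1.88
60,20,1,0.13
60,20,5,0.63
60,20,10,1.25
60,20,15,1.87
60,20,20,2.48
60,20,25,3.09
70,5,1,0.01
70,5,5,0.07
70,5,10,0.14
70,5,15,0.21
70,5,20,0.28
70,5,25,0.35
70,10,1,0.06
70,10,5,0.28
70,10,10,0.55
70,10,15,0.83
70,10,20,1.10
70,10,25,1.38
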