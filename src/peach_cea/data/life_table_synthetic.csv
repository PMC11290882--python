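age,sex,qx
16,male,0.000601
16,female,0.000540
17,male,0.000619
17,female,0.000553
18,male,0.000639
18,female,0.000567
19,male,0.000660
19,female,0.000582
20,male,0.000684
20,female,0.000599
21,male,0.000709
21,female,0.000617
22,male,0.000738
22,female,0.000636
23,male,0.000768
23,female,0.000658
24,male,0.000801
24,female,0.000681
25,male,0.000838
25,female,0.000706
26,male,0.000877
26,female,0.000734
27,male,0.000920
27,female,0.000764
28,male,0.000968
28,female,0.000797
29,male,0.001019
29,female,0.000833
30,male,0.001075
30,female,0.000873
31,male,0.001136
31,female,0.000915
32,male,0.001203
32,female,0.000962
33,male,0.001275
33,female,0.001013
34,male,0.001355
34,female,0.001068
35,male,0.001441
35,female,0.001129
36,male,0.001535
36,female,0.001195
37,male,0.001638
37,female,0.001267
38,male,0.001750
38,female,0.001345
39,male,0.001872
39,female,0.001431
40,male,0.002005
40,female,0.001524
41,male,0.002151
41,female,0.001626
42,male,0.002309
42,female,0.001736
43,male,0.002482
43,female,0.001857
44,male,0.002670
44,female,0.001989
45,male,0.002876
45,female,0.002133
46,male,0.003100
46,female,0.002290
47,male,0.003344
47,female,0.002461
48,male,0.003611
48,female,0.002648
49,male,0.003901
49,female,0.002851
50,male,0.004218
50,female,0.003073
51,male,0.004564
51,female,0.003315
52,male,0.004941
52,female,0.003579
53,male,0.005352
53,female,0.003866
54,male,0.005800
54,female,0.004180
55,male,0.006289
55,female,0.004522
56,male,0.006822
56,female,0.004895
57,male,0.007403
57,female,0.005302
58,male,0.008037
58,female,0.005746
59,male,0.008728
59,female,0.006230
60,male,0.009482
60,female,0.006757
61,male,0.010304
61,female,0.007333
62,male,0.011200
62,female,0.007960
63,male,0.012177
63,female,0.008644
64,male,0.013243
64,female,0.009390
65,male,0.014406
65,female,0.010204
66,male,0.015674
66,female,0.011091
67,male,0.017056
67,female,0.012059
68,male,0.018563
68,female,0.013114
69,male,0.020207
69,female,0.014265
70,male,0.022000
70,female,0.015520
71,male,0.023955
71,female,0.016888
72,male,0.026087
72,female,0.018381
73,male,0.028412
73,female,0.020008
74,male,0.030947
74,female,0.021783
75,male,0.033712
75,female,0.023718
76,male,0.036727
76,female,0.025829
77,male,0.040015
77,female,0.028130
78,male,0.043600
78,female,0.030640
79,male,0.047510
79,female,0.033377
80,male,0.051774
80,female,0.036362
81,male,0.056423
81,female,0.039616
82,male,0.061494
82,female,0.043166
83,male,0.067024
83,female,0.047036
84,male,0.073053
84,female,0.051257
85,male,0.079629
85,female,0.055860
86,male,0.086800
86,female,0.060880
87,male,0.094620
87,female,0.066354
88,male,0.103147
88,female,0.072323
89,male,0.112447
89,female,0.078833
90,male,0.122588
90,female,0.085932
91,male,0.133647
91,female,0.093673
92,male,0.145707
92,female,0.102115
93,male,0.158858
93,female,0.111321
94,male,0.173200
94,female,0.121360
95,male,0.188840
95,female,0.132308
96,male,0.205895
96,female,0.144246
97,male,0.224494
97,female,0.157266
98,male,0.244776
98,female,0.171463
99,male,0.266894
99,female,0.186946
100,male,0.291014
100,female,0.203830
101,male,0.317317
101,female,0.222242
102,male,0.346000
102,female,0.242320
103,male,0.377279
103,female,0.264216
104,male,0.411390
104,female,0.288093
105,male,0.448588
105,female,0.314131
106,male,0.489152
106,female,0.342527
107,male,0.533388
107,female,0.373492
108,male,0.581628
108,female,0.407259
109,male,0.634233
109,female,0.444083
110,male,1.000000
110,female,1.000000
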