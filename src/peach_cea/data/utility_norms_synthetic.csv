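age_low,age_high,sex,utility
16,24,male,0.924
16,24,female,0.924
25,34,male,0.914
25,34,female,0.914
35,44,male,0.894
35,44,female,0.894
45,54,male,0.834
45,54,female,0.834
55,64,male,0.784
55,64,female,0.794
65,74,male,0.764
65,74,female,0.764
75,110,male,0.734
75,110,female,0.694
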