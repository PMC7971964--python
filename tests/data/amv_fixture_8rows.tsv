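insomnia	met_x	age	sex	BMI
0	-0.31	52.1	0	24.8
1	0.84	61.3	1	28.9
0	0.12	47.6	1	22.4
1	0.55	58.0	0	31.2
0	-0.92	65.4	0	25.1
1	1.23	49.9	1	27.7
0	-0.44	55.2	1	23.6
1	0.07	60.8	0	29.3
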