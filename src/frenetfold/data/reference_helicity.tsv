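# synthetic stylized reference: alpha-helicity vs temperature (Celsius)
# logistic, midpoint 75 C, 10-90% width 40 C, plateaus 0.72 -> 0.08
temperature_celsius	helicity
0.0	0.719831
5.0	0.719707
10.0	0.719494
15.0	0.719123
20.0	0.718483
25.0	0.717377
30.0	0.715471
35.0	0.712195
40.0	0.706601
45.0	0.697143
50.0	0.681419
55.0	0.656000
60.0	0.616710
65.0	0.560000
70.0	0.485744
75.0	0.400000
80.0	0.314256
85.0	0.240000
90.0	0.183290
95.0	0.144000
100.0	0.118581
105.0	0.102857
110.0	0.093399
115.0	0.087805
120.0	0.084529
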