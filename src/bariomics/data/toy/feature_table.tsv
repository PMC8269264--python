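id	S01_A	S01_B	S02_A	S02_B	S03_A	S03_C	S04_A	S04_D	S05_A	S05_E	S06_A	S07_B	S08_A	L01_H	L02_H	L03_H	L04_H
F1	2.0	4.0	0.0	2.0	6.0	2.0	4.0	2.0	0.0	2.0	4.0	6.0	2.0	4.0	2.0	0.0	2.0
F2	4.0	2.0	2.0	4.0	2.0	4.0	2.0	4.0	2.0	4.0	2.0	2.0	4.0	2.0	4.0	2.0	4.0
F3	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0
F4	0.9	0.0	0.0	9.9	0.0	0.0	0.0	0.0	0.0	0.5	0.0	0.0	0.0	0.0	0.0	0.2	0.0
F5	0.0	1.0	2.0	3.0	4.0	5.0	6.0	7.0	8.0	9.0	0.9	9.9	1.0	2.0	3.0	4.0	5.0
F6	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0	5.0
F7	0.9	9.9	0.0	0.9	9.9	0.0	0.9	9.9	0.0	0.9	9.9	0.0	0.9	9.9	0.0	0.9	9.9
F8	1.0	0.0	3.0	0.0	5.0	0.0	7.0	0.0	9.0	0.0	2.0	0.0	4.0	0.0	6.0	0.0	8.0
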