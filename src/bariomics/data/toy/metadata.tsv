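sample_id	subject_id	timepoint	bmi	a1c	age	gender	bmi_6m	bmi_12m	bmi_18m
S01_A	S01	A	43.3	6.5	52	1	33.0		
S01_B	S01	B	41.1	6.4	52	1	33.0		
S02_A	S02	A	39.8	6.9	45	0	30.5		
S02_B	S02	B	38.0	6.7	45	0	30.5		
S03_A	S03	A	47.2		61	1	35.1		
S03_C	S03	C	44.0		61	1	35.1		
S04_A	S04	A	36.4	5.9	33	1	28.0		
S04_D	S04	D	30.2	5.6	33	1	28.0		
S05_A	S05	A	51.0	7.2	58	0	38.9		
S05_E	S05	E	38.9	6.1	58	0	38.9		
S06_A	S06	A	42.5	6.3	49	1			
S07_B	S07	B	40.7	6.6	38	0			
S08_A	S08	A	44.9	6.8	55	1			
L01_H	L01	H	22.1	4.7	29	0			
L02_H	L02	H	23.8	4.5	41	1			
L03_H	L03	H	20.9	4.9	35	1			
L04_H	L04	H	24.6	4.4	27	0			
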