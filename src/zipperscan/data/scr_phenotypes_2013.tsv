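genotype	tissue	mean	sem
Scr+/pb34	sex_comb	6.2	0.1
Scr14/pb34	sex_comb	2.5	0.1
Scr14/Scr+	sex_comb	7.0	0.1
Scr14/Scr13A	sex_comb	1.9	0.1
Scr14/Scr6	sex_comb	7.1	0.2
Scr+/pb34	pseudotrachea	5.3	0.1
Scr14/pb34	pseudotrachea	3.0	0.1
Scr14/Scr+	pseudotrachea	6.0	0.1
Scr14/Scr13A	pseudotrachea	4.8	0.2
Scr14/Scr6	pseudotrachea	6.0	0.0
Scr+/pb34	salivary_gland	108.7	3.1
Scr14/pb34	salivary_gland	100.5	3.2
Scr14/Scr+	salivary_gland	110.1	3.3
Scr14/Scr13A	salivary_gland	102.5	4.5
Scr14/Scr6	salivary_gland	108.4	3.1
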