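genotype	tissue	mean	sem
Scr+/pb34	sex_comb	6.3	0.2
Scr14/pb34	sex_comb	7.0	0.3
Scr14/Scr+	sex_comb	6.9	0.2
Scr14/Scr13A	sex_comb	2.6	0.1
Scr14/Scr6	sex_comb	6.3	0.2
Scr+/pb34	pseudotrachea	5.5	0.1
Scr14/pb34	pseudotrachea	5.4	0.3
Scr14/Scr+	pseudotrachea	5.5	0.1
Scr14/Scr13A	pseudotrachea	5.2	0.1
Scr14/Scr6	pseudotrachea	5.9	0.1
Scr+/pb34	salivary_gland	117.7	3.9
Scr14/pb34	salivary_gland	114.8	3.2
Scr14/Scr+	salivary_gland	112.8	3.0
Scr14/Scr13A	salivary_gland	123.6	2.7
Scr14/Scr6	salivary_gland	126.0	5.9
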