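outcome	factors	coverage_pct	accuracy_pct	rules	val_rules	valid
Allergic asthma	20	94.1	61.2	73	20	18
Asthma	16	93.2	62.6	66	16	14
Non-allergic asthma	16	95.8	64.0	72	16	16
Current asthma	19	93.0	63.2	39	12	10
Atopic sensitization >3.5 kU/L	14	88.4	64.0	51	7	7
Atopic sensitization >0.35 kU/L	3	17.3	59.0	3	0	0
Allergic eczema	24	95.0	67.4	83	17	17
Eczema	11	65.3	61.7	30	17	15
Non-allergic eczema	8	69.5	59.7	43	9	9
Rhinoconjunctivitis	18	87.1	63.8	41	14	13
Wheeze	16	82.1	60.8	59	15	13
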