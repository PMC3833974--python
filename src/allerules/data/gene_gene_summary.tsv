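outcome	material	factors	coverage_pct	accuracy_pct	rules	val_rules	valid
Allergic asthma	BAMSE	13	92.3	57.0	61	4	3
Allergic asthma	PARSIFAL	8	79.6	53.4	18	0	0
Non-allergic asthma	BAMSE	16	92.7	58.2	70	2	2
Non-allergic asthma	PARSIFAL	10	84.9	56.3	37	1	1
Asthma	BAMSE	9	47.2	56.6	21	2	2
Asthma	PARSIFAL	17	95.3	52.0	111	1	1
Current asthma	BAMSE	12	76.4	56.0	34	3	3
Current asthma	PARSIFAL	9	94.4	56.5	53	4	3
Atopic sensitization >3.5 kU/L	BAMSE	4	4.2	67.7	3	1	1
Atopic sensitization >3.5 kU/L	PARSIFAL	6	18.7	47.5	3	1	1
Atopic sensitization >0.35 kU/L	BAMSE	18	93.6	50.2	124	1	0
Atopic sensitization >0.35 kU/L	PARSIFAL	21	93.9	49.2	184	0	0
Allergic eczema	BAMSE	5	33.2	57.1	11	1	1
Allergic eczema	PARSIFAL	8	46.2	56.9	29	1	1
Eczema	BAMSE	8	49.8	54.5	17	0	0
Eczema	PARSIFAL	11	73.2	56.2	45	3	2
Non-allergic eczema	BAMSE	10	92.0	56.1	41	2	0
Non-allergic eczema	PARSIFAL	7	23.5	58.8	7	2	2
Rhinoconjunctivitis	BAMSE	9	42.4	47.5	18	0	0
Rhinoconjunctivitis	PARSIFAL	5	16.4	61.5	7	1	1
Wheeze	BAMSE	18	90.5	57.4	121	6	5
Wheeze	PARSIFAL	21	93.8	52.9	106	3	2
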