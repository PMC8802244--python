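species	diversity	body_size	trophic_level	fecundity	propagule_size	maturity	lifespan	adult_lifespan	parental_care	hermaphroditism
Coryphoblennius galerita	0.00607	7	2.28	NA	3.3	1.5	6	4.5	nest_guarder	none
Coris julis	0.01172	27.2	3.24	169.81	0.63	1	7	6	none	protogynous
Dicentrarchus labrax	0.00375	102.15	3.47	12436.52	1.15	3	15	12	none	none
Diplodus puntazzo	0.00533	49.69	3.07	277.87	0.87	2	10	8	none	rudimentary
Hippocampus guttulatus	0.00313	19.8	3.5	1.21	12	0.5	5	4.5	brood_pouch	none
Lophius budegassa	0.00225	103	4.23	2304.03	1.88	7.5	21	13.5	none	none
Lithognathus mormyrus	0.00553	37.85	3.42	214.09	0.75	2	12	10	none	protandrous
Merluccius merluccius	0.00844	88.9	4.43	2294.54	1.07	3	11	8	none	none
Mullus surmuletus	0.01135	30.18	3.46	2569.32	0.86	1.5	6	4.5	none	none
Pagellus erythrinus	0.011	36	3.46	2280.46	0.77	2	8	6	none	protogynous
Serranus cabrilla	0.01205	30.8	3.68	37.97	0.91	2	6	4	none	none
Spondyliosoma cantharus	0.00478	35.7	3.27	425.62	2.1	3	10	7	nest_guarder	protogynous
Symphodus cinereus	0.0066	14.1	3.3	13.2	2.87	1.5	6	4.5	nest_guarder	none
Sardina pilchardus	0.01415	20.35	2.94	22.89	1.64	1	5	4	none	none
Syngnathus typhle	0.00859	26.2	3.75	0.38	20	1	3	2	brood_pouch	none
Sarda sarda	0.00896	68.9	4.34	15647.73	1.3	1	4	3	none	none
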