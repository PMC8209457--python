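library_id	tissue	condition	provenance	medium	n_sequences	n_otus	n_singletons	coverage_pct	chao1	ace	shannon	inverse_simpson
LB-NPK	leaf_blade	NPK	clone	-	175	42	20	88.6	63	105	3.1	15.3
LB-PK	leaf_blade	PK	clone	-	177	37	14	92.1	48	49	2.9	12.5
LB-K	leaf_blade	K	clone	-	167	35	16	90.4	55	76	2.9	11.9
PE-NPK	petiole	NPK	clone	-	145	40	17	88.3	59	59	3.2	17.9
PE-PK	petiole	PK	clone	-	178	35	18	89.9	73	90	2.9	13.6
PE-K	petiole	K	clone	-	178	31	12	93.3	44	52	2.6	8.0
TR-NPK	taproot	NPK	clone	-	152	70	47	69.1	224	164	3.7	25.8
TR-PK	taproot	PK	clone	-	164	72	49	70.1	170	291	3.6	16.1
TR-K	taproot	K	clone	-	178	71	42	76.4	133	197	3.7	25.1
LR-NPK	lateral_root	NPK	clone	-	180	97	61	66.1	199	318	4.3	79.0
LR-PK	lateral_root	PK	clone	-	135	75	52	61.5	186	300	4.0	54.8
LR-K	lateral_root	K	clone	-	151	85	58	61.6	212	378	4.2	67.0
LR-PK-R	lateral_root	PK	isolate	R2A	171	52	28	83.6	115	124	3.4	21.3
LR-PK-T	lateral_root	PK	isolate	TSA	148	48	24	83.8	73	102	3.3	15.5
LR-K-R	lateral_root	K	isolate	R2A	180	54	30	83.3	163	148	3.5	26.1
LR-K-T	lateral_root	K	isolate	TSA	166	48	28	83.1	86	97	3.1	11.8
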