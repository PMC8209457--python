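# Synthetic reconstruction: the published survey reports OTU-level percentages
# for the 12 clone libraries only. The isolate-collection side of the 14-OTU
# evidence fixture below is reconstructed from the survey's genus-level
# collection abundances where the genus is tabulated, and otherwise from the
# minimal presence implied by the isolate's existence (one colony, ~0.6%) in
# the collection indicated by its name prefix. Percentages, "0" = absent.
otu_id	LR-PK-R	LR-PK-T	LR-K-R	LR-K-T
OTU-69	0	1.4	0	4.8
OTU-96	0	0	0.6	0
OTU-166	2.9	0	7.8	0
OTU-218	0	0	0.6	0
OTU-272	16.4	24.3	9.4	33.1
OTU-329	0	2.7	0.6	3.0
OTU-86	0	0.7	1.1	0
OTU-87	0	0	7.2	0
OTU-170	6.4	0	6.1	0
OTU-189	0	0	0.6	0
OTU-191	13.5	0	7.2	0
OTU-199	0	0	0.6	0
OTU-226	0	0	0.6	0
OTU-301	4.1	0	1.1	0
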