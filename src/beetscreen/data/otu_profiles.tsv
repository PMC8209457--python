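otu_id	LB-NPK	LB-PK	LB-K	PE-NPK	PE-PK	PE-K	TR-NPK	TR-PK	TR-K	LR-NPK	LR-PK	LR-K	isolate	effect
OTU-69	0	0	0	0	0	0	0	0	0	0	0	0	Pantoea sp. RK126	inhibiting
OTU-96	0	0	0	0	0	0	0	0	0	0.6	4.4	2.0	Rhizobacter sp. RK021	inhibiting
OTU-166	0	0	0	0	0	0	0	1.2	1.7	2.2	3.7	2.0	Neorhizobium sp. RK064	inhibiting
OTU-218	0	0	0	0	0	0	2.6	1.8	4.5	0.6	0.7	0	Tardiphaga sp. RK140	inhibiting
OTU-272	0	0	0	0	0	0	0	0	0	1.7	0.7	0.7	Streptomyces sp. TP071	inhibiting
OTU-329	1.7	0	0	2.8	0	0	1.3	0	0.6	0	0	0	Bacillus sp. TP182	inhibiting
OTU-86	1.1	1.1	4.8	6.2	2.8	1.7	0.7	0.6	0.6	1.7	0	0	Variovorax sp. RK170	promoting
OTU-87	0	0	0	0	0	0	2.6	1.2	0.6	2.2	1.5	3.3	Polaromonas sp. RK103	promoting
OTU-170	0	0	0	0	0	0	0	0	0	0	0	0	Mesorhizobium sp. TP027	promoting
OTU-189	0	0	0	0	0	0	0.7	0	2.8	0	1.5	2.0	Sphingobium sp. RK166	promoting
OTU-191	0	0	0	0	0	0	0	0	0	0.6	1.5	1.3	Sphingomonas sp. RP195	promoting
OTU-199	0	0	0	0	0	0	0	0	0	0	0	0	Sphingopyxis sp. RK106	promoting
OTU-226	0	0	0	0	0	0	0	0	0	0	0.7	0	Asticcacaulis sp. RK043	promoting
OTU-301	0	0	0	0	0	0	0	0	0	0	0	0	Nocardioides sp. RP110	promoting
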