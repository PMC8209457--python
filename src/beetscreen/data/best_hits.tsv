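otu_id	isolate	effect	closest_species	identity_pct
OTU-301	Nocardioides sp. RP110	promoting	Nocardioides cavernae	100
OTU-272	Streptomyces sp. TP071	inhibiting	Streptomyces mirabilis	100
OTU-329	Bacillus sp. TP182	inhibiting	Bacillus gibsonii	100
OTU-226	Asticcacaulis sp. RK043	promoting	Asticcacaulis benevestitus	98
OTU-170	Mesorhizobium sp. TP027	promoting	Mesorhizobium chacoense	98
OTU-166	Neorhizobium sp. RK064	inhibiting	Neorhizobium galegae	100
OTU-189	Sphingobium sp. RK166	promoting	Sphingobium aromaticiconvertens	100
OTU-191	Sphingomonas sp. RP195	promoting	Sphingomonas asaccharolytica	100
OTU-199	Sphingopyxis sp. RK106	promoting	Sphingopyxis taejonensis	100
OTU-218	Tardiphaga sp. RK140	inhibiting	Tardiphaga robiniae	99
OTU-87	Polaromonas sp. RK103	promoting	Polaromonas ginsengisoli	100
OTU-86	Variovorax sp. RK170	promoting	Variovorax paradoxus	100
OTU-69	Pantoea sp. RK126	inhibiting	Pantoea ananatis	100
OTU-96	Rhizobacter sp. RK021	inhibiting	Methylibium petroleiphilum	99
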