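# Published mass-cytometry cluster-abundance test summaries from the BioRRA
# DMARD-cessation cohort (20 flare, 16 drug-free-remission patients).
# median_pct_1 / median_pct_2: median % abundance in the first / second arm
# of the contrast; p_adj: BH-adjusted p. Only significant rows were
# published; absent (contrast, cluster) entries are not significant.
contrast	cluster_id	median_pct_1	median_pct_2	p_adj
FlareV_vs_FlareB	CD4_1	0.45	0.24	5.9e-4
FlareV_vs_FlareB	CD8_2	0.37	0.07	6.3e-9
FlareV_vs_FlareB	CD8_4	1.96	0.60	4.4e-11
FlareV_vs_FlareB	BC_1	0.13	0.03	5.9e-4
FlareV_vs_FlareB	CD4_3	0.43	0.27	1.7e-5
FlareV_vs_FlareB	GDT_3	0.95	0.73	1.2e-4
FlareV_vs_FlareB	DC_2	1.10	1.54	2.9e-3
RemV_vs_RemB	CD8_2	0.13	0.05	7.0e-4
RemV_vs_RemB	CD8_4	0.99	0.55	5.8e-4
RemV_vs_RemB	CD4_2	0.05	0.07	0.042
RemV_vs_RemB	CD4_3	0.42	0.26	0.042
FlareV_vs_RemV	CD4_1	0.45	0.29	5.7e-3
FlareV_vs_RemV	CD8_2	0.37	0.13	9.4e-4
FlareV_vs_RemV	CD8_4	1.96	0.99	4.6e-3
FlareV_vs_RemV	BC_2	1.20	1.96	0.029
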