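# Published V(D)J summary counts from the BioRRA scRNAseq cohort: unique
# clonal paired-CDR3 sequences, cells belonging to any clone, and total
# cells with a complete paired CDR3, per receptor compartment.
compartment	unique_clones	clonal_cells	total_cells
CD4	1021	4618	40783
CD8	1532	8850	25520
B	262	618	15302
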