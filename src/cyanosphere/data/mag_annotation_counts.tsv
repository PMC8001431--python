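genome	genome_size_bp	coding_bp	gc_bp	contig_count	total_genes	protein_coding_genes	rna_genes	pseudo_genes	genes_with_function	genes_with_cogs	genes_with_pfam	genes_with_signal_peptides	genes_with_tm_helices	crispr_repeats
Stigonema_ocellatum	10354468	7983295	4535257	509	8824	8701	3	120	2826	4011	5985	664	708	13
Chlorogloea_purpurea	4737903	4140927	2146270	228	4429	4384	2	43	1931	2250	3249	350	449	10
Gomphosphaeria_aponina	5337155	4360456	2081490	749	5305	5235	2	68	1846	2413	3751	446	378	19
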