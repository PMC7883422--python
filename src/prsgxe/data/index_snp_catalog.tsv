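# Published site-specific PRS compositions: index SNPs, risk alleles and
# risk-allele frequencies, as printed in the source table. Note: rs914153 is
# listed here on chromosome 2 as printed, although the accompanying text
# places it at 21q21; the printed table is stored unchanged and the
# discrepancy flagged here. The `source` column is our annotation (the rare
# variant rs370055571, freq 0.01, came from exome sequencing; the rest from
# the common-variant GWAS); catalog_p is not printed and left NA.
snp_id	gene	risk_allele	risk_allele_freq	chrom	pos	outcome	source	catalog_p	proxy_id
rs452369	SLC8A1	A	0.24	2	40157593	TBBMD	gwas_common	NA	NA
rs529125	SUPT3H	A	0.87	6	44829351	TBBMD	gwas_common	NA	NA
rs2800718	LOC105377989	A	0.21	6	127079180	TBBMD	gwas_common	NA	NA
rs10953178	SEM1	G	0.36	7	96501326	TBBMD	gwas_common	NA	NA
rs950083	NA	C	0.74	10	122717980	TBBMD	gwas_common	NA	NA
rs12273330	DGKZ	A	0.03	11	46340356	TBBMD	gwas_common	NA	NA
rs4394609	NA	A	0.93	1	22406025	TBBMD	gwas_common	NA	NA
rs914153	NA	A	0.70	2	138980535	TBBMD	gwas_common	NA	NA
rs370055571	MAP4K3	A	0.01	2	39258582	TBBMD	exome	NA	NA
rs9846561	LEKR1	A	0.96	3	157040993	LSBMD	gwas_common	NA	NA
rs16934799	KCNMA1	A	0.98	10	77448298	LSBMD	gwas_common	NA	NA
rs2087058	LOC105369777	G	0.54	12	54199621	LSBMD	gwas_common	NA	NA
rs1286083	RPS6KA5	G	0.12	14	90976435	LSBMD	gwas_common	NA	NA
rs7071206	NA	A	0.75	10	77641558	LSBMD	gwas_common	NA	NA
rs6684375	NA	G	0.90	1	22379941	LSBMD	gwas_common	NA	NA
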