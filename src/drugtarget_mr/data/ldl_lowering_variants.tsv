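# LDL-cholesterol-lowering variants for the HMGCR / PCSK9 / NPC1L1 cis scores.
# Per-effect-allele betas (mmol/L) with SE back-derived from the published 95% CI
# as (hi - lo) / (2 * 1.959964). Other alleles (OA) and EAF are NOT published for
# these variants: OA entries are synthetic non-palindromic placeholders and EAF is NA.
# SCORE labels the cis gene score each variant belongs to (hg19 coordinates).
SNP	CHR	BP	EA	OA	EAF	BETA	SE	P	N	SCORE
rs12916	5	74656539	T	C	NA	-0.073	0.0038266	7.790000e-78	188578	HMGCR
rs17648288	5	74696638	C	T	NA	-0.057	0.00612256	4.600000e-20	188578	HMGCR
rs3857388	5	74620377	T	C	NA	-0.042	0.00586745	2.200000e-11	188578	HMGCR
rs10064936	5	74536723	C	T	NA	-0.035	0.00612256	1.780000e-09	188578	HMGCR
rs11206510	1	55496039	C	T	NA	-0.083	0.00510213	2.380000e-53	188578	PCSK9
rs2479409	1	55504650	A	G	NA	-0.064	0.00408171	2.520000e-50	188578	PCSK9
rs585131	1	55524116	C	T	NA	-0.064	0.00510213	2.700000e-35	188578	PCSK9
rs11206514	1	55516004	C	A	NA	-0.051	0.00408171	9.950000e-33	188578	PCSK9
rs2495477	1	55518467	C	T	NA	-0.064	0.00561235	7.290000e-30	188578	PCSK9
rs2479394	1	55486064	A	G	NA	-0.039	0.00408171	1.580000e-19	188578	PCSK9
rs10493176	1	55538552	G	T	NA	-0.078	0.0102043	2.540000e-14	188578	PCSK9
rs602705	1	55525726	T	C	NA	-0.051	0.00688788	5.060000e-13	188578	PCSK9
rs2073547	7	44582331	A	G	NA	-0.049	0.00484703	1.920000e-21	188578	NPC1L1
rs217386	7	44600695	A	G	NA	-0.036	0.0038266	1.200000e-19	188578	NPC1L1
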