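cell_line	protein_change	alt_reads	ref_reads	tp53_mrna	cn_ratio	signature_prediction	observed_sensitivity
KASUMI-1	p.R248Q	52	0	265	0.54	insensitive	insensitive
COLO-818	p.C135R	34	0	257	1.14	insensitive	insensitive
IGR-37	p.C229fs	110	11	9	0.59	insensitive	insensitive
HCC202	p.T284fs	35	4	14	0.8	insensitive	insensitive
EFM-192A	p.F270fs	7	1	10	0.74	insensitive	insensitive
NCI-H1568	p.H179R	89	1	202	0.82	insensitive	insensitive
COLO-783	p.P27L	38	0	304	1.05	sensitive	insensitive
GA-10	p.I232N	94	50	493	0.81	insensitive	insensitive
GA-10	p.P152L	52	76	493	0.81	insensitive	insensitive
VMRC-RCW	p.I332_splice	192	68	63	1.65	insensitive	insensitive
JHH-5	p.PPQH190del	107	41	272	1.03	insensitive	insensitive
HDLM-2				1	0.94	insensitive	insensitive
RERF-LC-KJ				25	1.3	insensitive	insensitive
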