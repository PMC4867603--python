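uniprot_id	site	gene_name	protein_description	log_fold_change	fdr
D3YUK4	S21	NDUFB10	NADH dehydrogenase 1 beta subcomplex subunit 10	-2.84644	0.06
D3YWI1	S46	ALDOA	Fructose-bisphosphate aldolase	-1.1455	0.02
D3YYI5	T185	GM7293	Glyceraldehyde-3-phosphate dehydrogenase	-1.28977	0.01
D3Z1Z2	S79	ACSBG1	Long-chain-fatty-acid--CoA ligase ACSBG1 (Fragment)	-1.3143	0.00
D3Z7K3	S81	ABHD5	1-acylglycerol-3-phosphate O-acyltransferase ABHD5	-2.70938	0.08
E9Q4M2	S964	LIPE	Hormone-sensitive lipase	-2.22608	0.00
P19096	T976	FASN	Fatty acid synthase	-2.49298	0.01
P21550	Y44	ENO3	Beta-enolase	-2.656	0.07
P35486	S293	PDHA1	Pyruvate dehydrogenase E1 component subunit alpha	-1.55234	0.00
P50136	S334	BCKDHA	2-oxoisovalerate dehydrogenase subunit alpha	-1.84521	0.00
P50136	S344	BCKDHA	2-oxoisovalerate dehydrogenase subunit alpha	-3.54903	0.00
P51881	T84	SLC25A5	ADP/ATP translocase 2	-1.60139	0.02
Q05920	S981	PC	Pyruvate carboxylase, mitochondrial	-1.8856	0.02
Q80W21	S67	GSTM7	Glutathione S-transferase Mu 7	-3.09025	0.00
Q91V92	S1090	ACLY	ATP-citrate synthase	-3.97462	0.00
Q91V92	S653	ACLY	ATP-citrate synthase	-2.31841	0.00
Q91V92	S455	ACLY	ATP-citrate synthase	-1.43548	0.00
Q91V92	S455	ACLY	ATP-citrate synthase	-1.5408	0.00
Q91V92	S455	ACLY	ATP-citrate synthase	-2.31553	0.00
Q93092	S237	TALDO1	Transaldolase	-1.05461	0.01
Q9D0F9	T115;S117	PGM1	Phosphoglucomutase-1	-1.6288	0.00
Q9QXG4	S263;S267	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-4.66568	0.00
Q9QXG4	S263	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-2.35304	0.00
Q9QXG4	S265	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-2.67187	0.09
Q9QXG4	S267	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-2.89549	0.00
Q9QXG4	S30	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-1.01133	0.00
Q9QXG4	S30	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-1.72835	0.00
Q9QXG4	S30	ACSS2	Acetyl-coenzyme A synthetase, cytoplasmic	-1.97938	0.00
Q9R0Q7	S148;S151	PTGES3	Prostaglandin E synthase 3	-2.12365	0.00
Q9WVL0	S181	GSTZ1	Maleylacetoacetate isomerase	-2.85077	0.04
Q9Z1E4	S412	GYS1	Glycogen [starch] synthase, muscle	-1.95052	0.03
Q9Z1E4	S645	GYS1	Glycogen [starch] synthase, muscle	-2.03131	0.00
V9GWS1	S47;S49	ACACA	Acetyl-CoA carboxylase 1	-3.42496	0.00
V9GWS1	S47	ACACA	Acetyl-CoA carboxylase 1	-3.90682	0.00
V9GWS1	S23;S29	ACACA	Acetyl-CoA carboxylase 1	-2.81326	0.00
V9GWS1	S23	ACACA	Acetyl-CoA carboxylase 1	-1.64467	0.00
V9GWS1	S29	ACACA	Acetyl-CoA carboxylase 1	-2.6459	0.00
V9GWS1	S79	ACACA	Acetyl-CoA carboxylase 1	-2.1929	0.00
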