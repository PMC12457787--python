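family	stage	n_reads	ratio_percent
VINE1	Raw data	94648193	100.00
VINE1	Adaptor removal and QV (>=30) filtering	94624449	99.97
VINE1	Trimming to specific length (50 bp)	86411790	91.30
VINE1	QV (>=30) filtering	42861048	45.28
VINE1	Outlier filtering	29204663	30.86
Gret1	Raw data	86034789	100.00
Gret1	Adaptor removal and QV (>=30) filtering	86014185	99.98
Gret1	Trimming to specific length (50 bp)	80945543	94.08
Gret1	QV (>=30) filtering	31863975	37.04
Gret1	Outlier filtering	21313387	24.77
Tvv1	Raw data	149157571	100.00
Tvv1	Adaptor removal and QV (>=30) filtering	149125620	99.98
Tvv1	Trimming to specific length (50 bp)	138271067	92.70
Tvv1	QV (>=30) filtering	68316307	45.80
Tvv1	Outlier filtering	44211634	29.64
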