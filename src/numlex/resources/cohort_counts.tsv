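phrase1	n_phrase1_only	n_both	n_phrase2_only	phrase2
citrullinemia type 1	2	1	1	citrullinemia type I
type 2 diabetes mellitus	43777	7919	6053	type II diabetes mellitus
type 1 neurofibromatosis	181	56	77	type I neurofibromatosis
Tanner Stage 3	7639	1373	12367	Tanner Stage III
grade 3 anaplastic astrocytoma	42	27	40	grade III anaplastic astrocytoma
stage 3 chronic kidney disease	615	446	2190	stage III chronic kidney disease
factor 9 deficiency	14	51	139	factor IX deficiency
class 3 malocclusion	135	115	1079	class III malocclusion
phase 1 clinical trial	320	263	1158	phase I clinical trial
Mallampati score: 4	121	1	47	Mallampati score: IV
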