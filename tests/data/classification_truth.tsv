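# Hand-enumerated classification truth table.
# context: autosomal (diploid dosages 0/1/2) or x_male (proband and father
# hemizygous 0/1, mother diploid 0/1/2).
# model/transmitting/consistent are the expected classifier outputs under
# default config.
context	proband	father	mother	model	transmitting_parent	consistent
autosomal	0	0	0	unclassified		1
autosomal	0	0	1	unclassified		1
autosomal	0	0	2	unclassified		0
autosomal	0	1	0	unclassified		1
autosomal	0	1	1	unclassified		1
autosomal	0	1	2	unclassified		0
autosomal	0	2	0	unclassified		0
autosomal	0	2	1	unclassified		0
autosomal	0	2	2	unclassified		0
autosomal	1	0	0	de_novo		1
autosomal	1	0	1	autosomal_dominant	mother	1
autosomal	1	0	2	unclassified		1
autosomal	1	1	0	autosomal_dominant	father	1
autosomal	1	1	1	unclassified		1
autosomal	1	1	2	unclassified		1
autosomal	1	2	0	unclassified		1
autosomal	1	2	1	unclassified		1
autosomal	1	2	2	unclassified		0
autosomal	2	0	0	de_novo		0
autosomal	2	0	1	unclassified		0
autosomal	2	0	2	unclassified		0
autosomal	2	1	0	unclassified		0
autosomal	2	1	1	autosomal_recessive	both	1
autosomal	2	1	2	unclassified		1
autosomal	2	2	0	unclassified		0
autosomal	2	2	1	unclassified		1
autosomal	2	2	2	unclassified		1
x_male	0	0	0	unclassified		1
x_male	0	0	1	unclassified		1
x_male	0	0	2	unclassified		0
x_male	0	1	0	unclassified		1
x_male	0	1	1	unclassified		1
x_male	0	1	2	unclassified		0
x_male	1	0	0	de_novo		1
x_male	1	0	1	x_linked	mother	1
x_male	1	0	2	x_linked	mother	1
x_male	1	1	0	unclassified		0
x_male	1	1	1	x_linked	mother	1
x_male	1	1	2	x_linked	mother	1
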