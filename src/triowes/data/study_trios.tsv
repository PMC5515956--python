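trio_id	proband_sex	sibling_sex	consanguineous	note
ASD-9	male		0
ASD-16	female		1
ASD-17	male	male	1
ASD-18	male		1
ASD-19	male		0
ASD-21	male		1
ASD-24	male	male	0
ASD-37	male	female	0
ASD-38	male		0
ASD-39	male		0
ASD-40	male		1
ASD-43	male		1
ASD-52	male		1	consanguinity flag synthetic: cohort total is 9/19 but per-family flags are unpublished; 8 assigned from printed ROH intervals, this one completes the count
ASD-55	male		0
ASD-58	male		0
ASD-64	female		0
ASD-66	male		0
ASD-69	male	male	1
ASD-73	male		1
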