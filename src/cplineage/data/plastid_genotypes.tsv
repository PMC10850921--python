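label	region	cpINDEL2	cpINDEL3	cpINDEL7	cpINDEL9	cpINDEL10	cpINDEL12	cpINDEL13	cpINDEL17	cpINDEL19	T. incisa	T. japonica	T. natans	T. bispinosa
incisa A	Japan	5	1	1	1	2	2	2	1	1	2	0	0	0
incisa B	Japan	2	3	3	1	2	2	1	2	2	2	0	0	0
W	Japan	1	3	2	2	1	3	2	1	1	0	5	0	0
W	China	1	3	2	2	1	3	2	1	1	0	11	0	0
natans-bispinosa 1	China	1	2	2	2	1	2	2	1	1	0	0	5	0
natans-bispinosa 2	China	2	1	1	1	2	1	2	1	1	0	0	1	6
natans-bispinosa 3	China	2	1	2	1	2	2	2	1	1	0	0	0	2
natans-bispinosa 4	Japan	3	1	1	1	2	2	2	1	1	0	0	3	4
natans-bispinosa 5	China	3	1	1	1	2	2	2	1	1	0	0	1	5
natans-bispinosa 6	China	3	2	2	1	2	2	2	1	1	0	0	0	3
natans-bispinosa 7	Japan	4	2	1	1	2	1	2	1	1	0	0	0	4
natans-bispinosa 8	China	4	2	1	1	2	1	2	1	1	0	0	0	25
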