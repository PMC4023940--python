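locus	na	he	ho	shannon_i
CCM1	9	0.7455	0.2171	1.5977
CCM2	6	0.0801	0.0597	0.2283
CCM19	4	0.2564	0.2340	0.5288
CCM25	8	0.5384	0.1929	1.0222
CCM27	13	0.4222	0.2587	0.8954
CCM29	4	0.3424	0.3885	0.6624
CCM40	6	0.4502	0.3372	0.9405
CCM46	7	0.6956	0.5059	1.4290
CCM49	7	0.5437	0.5075	0.9823
CCM56	13	0.6890	0.6815	1.5153
CCM65	4	0.5212	0.3583	0.8078
CCM66	6	0.2339	0.0800	0.5297
CCM83	9	0.3247	0.2939	0.6864
CCM108	8	0.5260	0.3360	0.9079
CCM118	9	0.7868	0.3386	1.6831
CCM125	7	0.4158	0.0075	0.7910
CCM149	5	0.0591	0.0361	0.1659
CCM154	6	0.6179	0.3431	1.1863
CCM180	9	0.7292	0.4826	1.4833
CCM189	7	0.5422	0.3034	1.0475
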