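EXPOSURE	OUTCOME	METHOD	NSNP	OR	CI_LOW	CI_HIGH	P	Q	Q_P	EGGER_INTERCEPT	EGGER_INTERCEPT_P
glycine	AD	ivw	19	1.145	0.939	1.396	0.180	33.030	0.017
glycine	AD	weighted_median	19	1.138	0.920	1.407	0.235
glycine	AD	egger	19	1.101	0.683	1.777	0.697			0.002	0.863
glycine	PD	ivw	23	0.929	0.737	1.170	0.531	34.654	0.042
glycine	PD	weighted_median	23	1.058	0.784	1.429	0.713
glycine	PD	egger	23	0.940	0.553	1.598	0.822			-0.001	0.960
glycine	ALS	ivw	23	1.003	0.945	1.066	0.916	21.103	0.514
glycine	ALS	weighted_median	23	1.002	0.939	1.070	0.945
glycine	ALS	egger	23	1.004	0.931	1.082	0.921			0.000	0.981
glutamate	AD	ivw	20	1.311	1.087	1.580	0.004	10.195	0.948
glutamate	AD	weighted_median	20	1.269	0.970	1.660	0.082
glutamate	AD	egger	20	1.190	0.816	1.737	0.378			0.004	0.573
glutamate	PD	ivw	21	0.843	0.645	1.100	0.209	15.623	0.740
glutamate	PD	weighted_median	21	0.840	0.575	1.227	0.368
glutamate	PD	egger	21	0.900	0.546	1.485	0.685			-0.003	0.764
glutamate	ALS	ivw	23	0.996	0.824	1.203	0.964	30.911	0.098
glutamate	ALS	weighted_median	23	1.027	0.823	1.282	0.812
glutamate	ALS	egger	23	1.631	1.161	2.291	0.010			-0.023	0.004
serotonin	AD	ivw	22	0.607	0.396	0.932	0.022	26.983	0.171
serotonin	AD	weighted_median	22	0.517	0.300	0.893	0.018
serotonin	AD	egger	22	1.010	0.222	4.587	0.990			-0.010	0.500
serotonin	PD	ivw	23	1.080	0.595	1.963	0.800	35.575	0.046
serotonin	PD	weighted_median	23	2.449	1.194	5.024	0.015
serotonin	PD	egger	23	1.025	0.121	8.689	0.982			0.001	0.960
serotonin	ALS	ivw	23	0.838	0.596	1.180	0.312	11.571	0.977
serotonin	ALS	weighted_median	23	0.899	0.563	1.434	0.654
serotonin	ALS	egger	23	0.472	0.102	2.176	0.346			0.011	0.457
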