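gene	log_fc	mirna	p_value	fold_change
CYP2E1	-1.4341	miR-335	0.0242	1.3300
CAV1	-0.8518	miR-34b	0.1753	185.3764
CAV1	-0.8518	miR-886-3p	0.0001	1.5645
CAV1	-0.8518	miR-218	0.0499	1.9012
CAV1	-0.8518	miR-576-3p	0.0453	2.1916
CAV2	-0.5386	miR-200c	0.0913	4.8313
CAV2	-0.5386	miR-576-3p	0.0453	2.1916
CEBPA	0.5812	miR-186	0.0017	0.8356
CREBBP	0.3821	miR-186	0.0017	0.8356
CREBBP	0.3821	miR-95	0.0216	0.6320
CREBBP	0.3821	miR-769	0.1249	0.8388
EGLN2	0.4574	miR-202	0.0396	0.5988
EGLN2	0.4574	let-7g	0.0435	0.8402
ITGA1	-0.3754	miR-616	0.0446	1.3337
ITGA1	-0.3754	miR-660	0.0297	1.2642
ITGA1	-0.3754	miR-576-3p	0.0453	2.1916
ITGA1	-0.3754	miR-335	0.0242	1.3300
THBS1	-0.3951	miR-886-3p	0.0001	1.5645
THBS1	-0.3951	miR-335	0.0242	1.3300
THBS1	-0.3951	miR-616	0.0446	1.3337
THBS1	-0.3951	miR-92a	0.0169	1.1319
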