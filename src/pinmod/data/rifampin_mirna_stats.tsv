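mirna	p_value	direction
miR-886-3p	0.0002	up
miR-766	0.0075	up
miR-92a	0.0169	up
miR-107	0.0177	up
miR-30d#	0.0195	up
miR-335	0.0241	up
miR-660	0.0297	up
miR-638	0.0302	up
miR-25	0.0338	up
miR-616	0.0446	up
miR-576-3p	0.0453	up
miR-218	0.0499	up
miR-186	0.0018	down
miR-361	0.0111	down
miR-95	0.0219	down
miR-345	0.0239	down
miR-320	0.0376	down
miR-202	0.0396	down
miR-200b#	0.0426	down
let-7g	0.0435	down
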